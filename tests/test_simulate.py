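"""Generator contracts: determinism, realized rates, carried truth."""

import numpy as np
import pytest

from darkbin import simulate
from darkbin.seqio import gc_fraction
from darkbin.simulate import CohortSpec, GenomeSpec


def mismatch_fraction(a: str, b: str) -> float:
    return np.mean([x != y for x, y in zip(a, b)])


class TestEvolveGenomes:
    def test_zero_divergence_child_is_identical(self):
        anc = GenomeSpec(id="a", length=5000, gc_target=0.5)
        child = GenomeSpec(id="c", length=5000, gc_target=0.5, divergence_from_parent=0.0)
        genomes, truth = simulate.evolve_genome_set(anc, [child], seed=1)
        assert genomes["a"] == genomes["c"]
        assert truth.loc["a", "c"] == 0.0

    def test_realized_divergence_within_three_binomial_sd(self):
        p, L = 0.05, 100_000
        anc = GenomeSpec(id="a", length=L, gc_target=0.5)
        child = GenomeSpec(id="c", length=L, gc_target=0.5, divergence_from_parent=p)
        for seed in range(10):
            genomes, _ = simulate.evolve_genome_set(anc, [child], seed=seed)
            obs = mismatch_fraction(genomes["a"], genomes["c"])
            assert abs(obs - p) <= 3 * np.sqrt(p * (1 - p) / L)

    def test_same_seed_reproduces_byte_identical_genomes(self):
        anc = GenomeSpec(id="a", length=20_000, gc_target=0.4)
        kids = [GenomeSpec(id="c", length=20_000, gc_target=0.4, divergence_from_parent=0.1)]
        g1, _ = simulate.evolve_genome_set(anc, kids, seed=3)
        g2, _ = simulate.evolve_genome_set(anc, kids, seed=3)
        assert g1 == g2

    def test_truth_table_adds_along_paths(self):
        anc = GenomeSpec(id="a", length=2000, gc_target=0.5)
        kids = [
            GenomeSpec(id="b", length=2000, gc_target=0.5, divergence_from_parent=0.02),
            GenomeSpec(id="c", length=2000, gc_target=0.5, divergence_from_parent=0.03, parent="b"),
            GenomeSpec(id="d", length=2000, gc_target=0.5, divergence_from_parent=0.04),
        ]
        _, truth = simulate.evolve_genome_set(anc, kids, seed=0)
        assert truth.loc["a", "c"] == pytest.approx(0.05)
        assert truth.loc["c", "d"] == pytest.approx(0.03 + 0.02 + 0.04)
        assert np.allclose(truth.values, truth.values.T)

    def test_gc_target_realized_within_two_percent(self):
        for gc in (0.35, 0.5, 0.65):
            anc = GenomeSpec(id="a", length=20_000, gc_target=gc)
            genomes, _ = simulate.evolve_genome_set(anc, [], seed=11)
            assert abs(gc_fraction(genomes["a"]) - gc) <= 0.02

    def test_divergence_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            GenomeSpec(id="x", length=2000, gc_target=0.5, divergence_from_parent=0.5)
        with pytest.raises(ValueError):
            GenomeSpec(id="x", length=500, gc_target=0.5)


class TestFragmentToContigs:
    def test_single_contig_zero_cv_is_whole_genome_exact_coverage(self, rng):
        genome = simulate.random_genome(5000, 0.5, rng)
        (contig,) = simulate.fragment_to_contigs(genome, 1, 40.0, 0.0, 1000, seed=2)
        assert contig.seq == genome
        assert contig.coverage == 40.0

    def test_contigs_partition_genome_and_gc_matches_counting(self, rng):
        genome = simulate.random_genome(30_000, 0.4, rng)
        contigs = simulate.fragment_to_contigs(genome, 10, 30.0, 0.2, 1500, seed=5, source="g")
        assert "".join(c.seq for c in contigs) == genome
        assert sum(c.length for c in contigs) == len(genome)
        for c in contigs:
            brute = (c.seq.count("G") + c.seq.count("C")) / len(c.seq)
            assert c.gc == pytest.approx(brute)
            assert c.source == "g"

    def test_same_seed_identical_contig_set(self, rng):
        genome = simulate.random_genome(10_000, 0.5, rng)
        a = simulate.fragment_to_contigs(genome, 5, 20.0, 0.3, 1000, seed=9)
        b = simulate.fragment_to_contigs(genome, 5, 20.0, 0.3, 1000, seed=9)
        assert [(c.id, c.seq, c.coverage) for c in a] == [(c.id, c.seq, c.coverage) for c in b]

    def test_infeasible_fragmentation_rejected(self, rng):
        genome = simulate.random_genome(5000, 0.5, rng)
        with pytest.raises(ValueError):
            simulate.fragment_to_contigs(genome, 6, 20.0, 0.1, 1000, seed=1)


class TestCohort:
    def test_row_sums_equal_depth_exactly(self):
        spec = CohortSpec(n_patients=4, depth_per_sample=7919, seed=1)
        counts, metadata, truth = simulate.simulate_cohort(spec)
        assert (counts.sum(axis=1) == 7919).all()
        assert len(counts) == 4 * len(spec.sites) * 2
        assert set(metadata["disease_state"]) == {"diseased", "unaffected"}

    def test_every_patient_keeps_an_unaffected_site(self):
        spec = CohortSpec(n_patients=10, seed=3, depth_per_sample=1000)
        _, metadata, _ = simulate.simulate_cohort(spec)
        for _, grp in metadata.groupby("patient"):
            assert (grp["disease_state"] == "unaffected").sum() >= 1

    def test_truth_records_planted_multiplier(self):
        spec = CohortSpec(n_patients=3, effect_multiplier=2.5, seed=5, depth_per_sample=1000)
        _, metadata, truth = simulate.simulate_cohort(spec)
        diseased = metadata.index[metadata["disease_state"] == "diseased"]
        assert (truth.loc[diseased, "multiplier"] == 2.5).all()
        unaffected = metadata.index[metadata["disease_state"] == "unaffected"]
        assert (truth.loc[unaffected, "multiplier"] == 1.0).all()

    def test_no_effect_no_dispersion_draws_from_common_profile(self):
        spec = CohortSpec(
            n_patients=6, effect_multiplier=1.0, subject_sd=0.0, sample_sd=0.0,
            depth_per_sample=200_000, seed=8,
        )
        counts, _, _ = simulate.simulate_cohort(spec)
        rel = counts.div(counts.sum(axis=1), axis=0)
        base = simulate.DEFAULT_SKIN_PROFILE
        # every sample's profile sits at multinomial distance from the base
        for taxon, p in base.items():
            sd = np.sqrt(p * (1 - p) / 200_000)
            assert (np.abs(rel[taxon] - p) < 5 * sd).all()

    def test_subject_offsets_make_intra_patient_profiles_closer(self):
        from darkbin.diversity import bray_curtis

        closer = 0
        for seed in range(10):
            spec = CohortSpec(
                n_patients=6, effect_multiplier=1.0, subject_sd=1.5, sample_sd=0.3,
                depth_per_sample=5000, seed=seed,
            )
            counts, metadata, _ = simulate.simulate_cohort(spec)
            rel = counts.div(counts.sum(axis=1), axis=0)
            ids = list(counts.index)
            intra, inter = [], []
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    d = bray_curtis(rel.loc[ids[i]], rel.loc[ids[j]])
                    same = metadata.loc[ids[i], "patient"] == metadata.loc[ids[j], "patient"]
                    (intra if same else inter).append(d)
            closer += np.mean(intra) < np.mean(inter)
        assert closer == 10

    def test_base_profile_must_sum_to_one(self):
        with pytest.raises(ValueError):
            simulate.simulate_cohort(CohortSpec(seed=0), {"A": 0.5, "B": 0.2})


class TestMlstReads:
    @staticmethod
    def _alleles(rng):
        return {f"locus{i}": simulate.random_genome(400, 0.5, rng) for i in range(1, 4)}

    def test_error_free_reads_match_the_template_exactly(self, rng):
        alleles = self._alleles(rng)
        reads, truth = simulate.simulate_mlst_reads(alleles, error_rate=0.0, coverage=10, seed=4)
        for rid, seq in reads:
            locus = truth.loc[rid, "locus"]
            start = int(truth.loc[rid, "start"])
            allele = alleles[locus]
            # compare only the part of the read inside the locus
            lo = max(0, -start)
            hi = min(len(seq), len(allele) - start)
            if hi > lo:
                assert seq[lo:hi] == allele[start + lo : start + hi]

    def test_realized_error_rate_within_three_binomial_sd(self, rng):
        alleles = self._alleles(rng)
        p = 0.02
        errors = total = 0
        for seed in range(5):
            reads, truth = simulate.simulate_mlst_reads(
                alleles, error_rate=p, coverage=10, seed=seed
            )
            for rid, seq in reads:
                locus = truth.loc[rid, "locus"]
                start = int(truth.loc[rid, "start"])
                allele = alleles[locus]
                lo, hi = max(0, -start), min(len(seq), len(allele) - start)
                for k in range(lo, hi):
                    total += 1
                    errors += seq[k] != allele[start + k]
        obs = errors / total
        assert abs(obs - p) <= 3 * np.sqrt(p * (1 - p) / total)

    def test_per_locus_depth_within_twenty_percent(self, rng):
        alleles = self._alleles(rng)
        reads, truth = simulate.simulate_mlst_reads(alleles, coverage=15, seed=6)
        for locus, allele in alleles.items():
            depth = np.zeros(len(allele))
            sub = truth[truth["locus"] == locus]
            for rid in sub.index:
                start = int(sub.loc[rid, "start"])
                lo, hi = max(0, start), min(len(allele), start + 100)
                depth[lo:hi] += 1
            assert abs(depth.mean() - 15) / 15 <= 0.2

    def test_same_seed_identical_reads(self, rng):
        alleles = self._alleles(rng)
        a, _ = simulate.simulate_mlst_reads(alleles, seed=13)
        b, _ = simulate.simulate_mlst_reads(alleles, seed=13)
        assert a == b

    def test_error_rate_domain_enforced(self, rng):
        with pytest.raises(ValueError):
            simulate.simulate_mlst_reads(self._alleles(rng), error_rate=0.2, seed=1)
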