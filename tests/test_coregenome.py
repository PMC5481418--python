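"""Ortholog filters, core selection, concatenation, trimming, NJ trees."""

import numpy as np
import pytest

from darkbin import simulate
from darkbin.coregenome import (
    ConcatAlignment,
    OrthologHit,
    OrthologTable,
    build_concat_alignment,
    find_orthologs,
    nj_tree,
    pairwise_distances,
    rf_distance,
    select_core,
    trim_alignment,
)
from darkbin.simulate import GenomeSpec


def make_table(presence: dict[str, list[str]], genomes: list[str], gene_len: int = 600):
    """OrthologTable from a {gene: [genomes with a hit]} presence map."""
    table = OrthologTable(list(presence), genomes)
    for gene, carriers in presence.items():
        for g in carriers:
            table.add(OrthologHit(gene, g, "A" * gene_len, 0.95, gene_len))
    return table


class TestFindOrthologs:
    def test_short_gene_excluded_even_when_perfect(self, rng):
        genome = simulate.random_genome(20_000, 0.5, rng)
        genes = {"short": genome[1000:1500], "long": genome[3000:3700]}
        table = find_orthologs(genes, {"g": genome})
        assert table.get("short", "g") is None  # 500 bp is not > 500 bp
        assert table.get("long", "g") is not None

    def test_low_identity_hit_excluded(self, rng):
        genome = simulate.random_genome(20_000, 0.5, rng)
        gene = simulate.mutate(genome[2000:2800], 0.35, rng)  # ~65% identity
        table = find_orthologs({"gene": gene}, {"g": genome})
        assert table.get("gene", "g") is None

    def test_tiny_pangenome_matches_planted_presence(self, rng):
        """Exhaustive check on a planted 5-gene x 4-genome pangenome."""
        base = simulate.random_genome(30_000, 0.5, rng)
        genes = {f"gene{i}": base[i * 2000 : i * 2000 + 800] for i in range(5)}
        planted = {
            "gene0": ["g0", "g1", "g2", "g3"],
            "gene1": ["g0", "g1", "g2"],
            "gene2": ["g0", "g3"],
            "gene3": ["g1"],
            "gene4": [],
        }
        genomes = {}
        for gi in range(4):
            gid = f"g{gi}"
            parts = [simulate.random_genome(1500, 0.5, rng)]
            for gene_id, carriers in planted.items():
                if gid in carriers:
                    parts.append(simulate.mutate(genes[gene_id], 0.02, rng))
                    parts.append(simulate.random_genome(1000, 0.5, rng))
            genomes[gid] = "".join(parts)
        table = find_orthologs(genes, genomes)
        accepted = {
            gene: sorted(g for g in genomes if table.get(gene, g) is not None)
            for gene in genes
        }
        assert accepted == {g: sorted(c) for g, c in planted.items()}

    def test_empty_gene_set_rejected(self, rng):
        with pytest.raises(ValueError):
            find_orthologs({}, {"g": "ACGT" * 1000})


class TestSelectCore:
    def test_strict_95_percent_boundary(self):
        genomes = [f"g{i}" for i in range(20)]
        table = make_table(
            {"all": genomes, "nineteen": genomes[:19], "eighteen": genomes[:18]},
            genomes,
        )
        assert select_core(table) == ["all"]  # 19/20 = 0.95 exactly: excluded

    def test_monotone_in_prevalence_threshold(self):
        genomes = [f"g{i}" for i in range(10)]
        table = make_table(
            {"a": genomes, "b": genomes[:9], "c": genomes[:7], "d": genomes[:5]},
            genomes,
        )
        sizes = [
            len(select_core(table, min_prevalence=t)) for t in (0.0, 0.5, 0.7, 0.9, 0.99)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_core_is_an_error(self):
        genomes = ["g0", "g1"]
        table = make_table({"a": ["g0"]}, genomes)
        with pytest.raises(ValueError, match="core"):
            select_core(table)


class TestConcatAndTrim:
    def test_alignment_length_is_sum_of_gene_lengths(self, rng):
        anc = GenomeSpec(id="anc", length=30_000, gc_target=0.5)
        kids = [
            GenomeSpec(id=f"c{i}", length=30_000, gc_target=0.5, divergence_from_parent=0.03)
            for i in range(3)
        ]
        genomes, truth = simulate.evolve_genome_set(anc, kids, seed=21)
        genes = simulate.gene_windows(genomes["anc"], n_genes=10, gene_len=800)
        table = find_orthologs(genes, {g: genomes[g] for g in ["c0", "c1", "c2"]})
        core = select_core(table)
        aln = build_concat_alignment(core, table, genes)
        assert aln.n_columns == sum(len(genes[g]) for g in core)
        # pairwise mismatch fraction tracks the planted divergence
        dm = pairwise_distances(aln, model="p")
        for a in ["c0", "c1", "c2"]:
            for b in ["c0", "c1", "c2"]:
                if a != b:
                    assert dm.loc[a, b] == pytest.approx(truth.loc[a, b], abs=0.01)

    def test_missing_gene_becomes_all_gap_block(self):
        genomes = ["g0", "g1", "g2"]
        table = make_table({"a": genomes, "b": ["g0", "g1"]}, genomes, gene_len=600)
        aln = build_concat_alignment(["a", "b"], table, {"a": "A" * 600, "b": "C" * 600})
        assert aln.rows["g2"][600:] == "-" * 600

    def test_trim_gapless_alignment_unchanged(self):
        aln = ConcatAlignment(["a", "b"], {"a": "ACGTACGT", "b": "ACGTACGA"}, [("g", 0, 8)])
        trimmed = trim_alignment(aln)
        assert trimmed.rows == aln.rows

    def test_trim_removes_gappy_columns(self):
        rows = {f"r{i}": ("A" if i < 7 else "-") + "CCCC" for i in range(10)}
        aln = ConcatAlignment(list(rows), rows, [("g", 0, 5)])
        trimmed = trim_alignment(aln, max_gap_fraction=0.2)
        # column 0 has 3/10 gaps > 0.2 -> removed
        assert trimmed.n_columns == 4
        assert trimmed.block_bounds == [("g", 0, 4)]

    def test_trim_all_columns_removed_is_error(self):
        rows = {"a": "----", "b": "AAAA"}
        aln = ConcatAlignment(list(rows), rows, [("g", 0, 4)])
        with pytest.raises(ValueError):
            trim_alignment(aln, max_gap_fraction=0.2)


class TestTrees:
    def test_three_taxa_branch_lengths_solve_three_point_system(self):
        rows = {"a": "A" * 100, "b": "A" * 90 + "C" * 10, "c": "A" * 80 + "G" * 20}
        aln = ConcatAlignment(list(rows), rows, [("g", 0, 100)])
        tree = nj_tree(aln, model="p")
        import dendropy

        t = dendropy.Tree.get(data=tree, schema="newick")
        dist = {}
        pdm = t.phylogenetic_distance_matrix()
        for t1 in t.taxon_namespace:
            for t2 in t.taxon_namespace:
                dist[(t1.label, t2.label)] = pdm.distance(t1, t2)
        # path lengths on the tree reproduce the input distances exactly
        assert dist[("a", "b")] == pytest.approx(0.10, abs=1e-9)
        assert dist[("a", "c")] == pytest.approx(0.20, abs=1e-9)
        # b and c mismatch on the union of their mutated intervals: 20 sites
        assert dist[("b", "c")] == pytest.approx(0.20, abs=1e-9)

    def test_four_taxon_quartet_recovered(self):
        # ((a,b),(c,d)): ab and cd are close, the cross pairs distant
        rows = {
            "a": "A" * 200,
            "b": "A" * 190 + "C" * 10,
            "c": "G" * 100 + "A" * 100,
            "d": "G" * 100 + "A" * 90 + "T" * 10,
        }
        aln = ConcatAlignment(list(rows), rows, [("g", 0, 200)])
        tree = nj_tree(aln, model="p")
        assert rf_distance(tree, "((a,b),(c,d));") == 0
        assert rf_distance(tree, "((a,c),(b,d));") == 2

    def test_rf_distance_contracts(self):
        assert rf_distance("((a,b),(c,d));", "((a,b),(c,d));") == 0
        assert rf_distance("((a,b),(c,d));", "((a,c),(b,d));") == 2
        # star vs fully resolved 5-taxon tree: all internal edges differ
        assert rf_distance("(a,b,c,d,e);", "((a,b),((c,d),e));") == 2

    def test_rf_distance_leaf_mismatch_is_error(self):
        with pytest.raises(ValueError):
            rf_distance("((a,b),(c,d));", "((a,b),(c,e));")

    def test_nj_requires_three_rows(self):
        rows = {"a": "ACGT", "b": "ACGA"}
        aln = ConcatAlignment(list(rows), rows, [("g", 0, 4)])
        with pytest.raises(ValueError):
            nj_tree(aln)

    def test_jc_distance_undefined_at_saturation(self):
        rows = {"a": "A" * 100, "b": "C" * 100, "c": "A" * 100}
        aln = ConcatAlignment(list(rows), rows, [("g", 0, 100)])
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            nj_tree(aln, model="jc")


def random_planted_tree(rng, n_leaves, length=40_000, rate_lo=0.02, rate_hi=0.05):
    """A random bifurcating genealogy as GenomeSpecs plus its Newick string."""
    counter = {"i": 0}
    specs = []

    def build(leaves, parent):
        if len(leaves) == 1:
            leaf = leaves[0]
            rate = float(rng.uniform(rate_lo, rate_hi))
            specs.append(
                GenomeSpec(id=leaf, length=length, gc_target=0.5,
                           divergence_from_parent=rate, parent=parent)
            )
            return leaf
        counter["i"] += 1
        node = f"I{counter['i']}"
        rate = float(rng.uniform(rate_lo, rate_hi))
        specs.append(
            GenomeSpec(id=node, length=length, gc_target=0.5,
                       divergence_from_parent=rate, parent=parent)
        )
        split = int(rng.integers(1, len(leaves)))
        left = build(leaves[:split], node)
        right = build(leaves[split:], node)
        return f"({left},{right})"

    leaf_ids = [f"L{i}" for i in range(n_leaves)]
    split = int(rng.integers(1, n_leaves))
    left = build(leaf_ids[:split], None)
    right = build(leaf_ids[split:], None)
    newick = f"({left},{right});"
    return specs, leaf_ids, newick


def test_nj_recovers_planted_topologies_over_ten_seeds():
    """Planted 6-8 leaf genealogies are recovered exactly (RF = 0)."""
    for seed in range(10):
        rng = np.random.default_rng(3000 + seed)
        n_leaves = int(rng.integers(6, 9))
        specs, leaf_ids, newick = random_planted_tree(rng, n_leaves)
        anc = GenomeSpec(id="anc", length=40_000, gc_target=0.5)
        genomes, _ = simulate.evolve_genome_set(anc, specs, seed=seed)
        genes = simulate.gene_windows(genomes["anc"], n_genes=30, gene_len=800)
        table = find_orthologs(genes, {g: genomes[g] for g in leaf_ids})
        core = select_core(table)
        assert sum(len(genes[g]) for g in core) >= 20_000
        aln = build_concat_alignment(core, table, genes)
        tree = nj_tree(aln, model="jc")
        assert rf_distance(tree, newick) == 0
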