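"""Synthetic data generators with machine-readable ground truth.

Every generator is a pure function of its seed and emulates one input of
the analysis pipeline:

* :func:`evolve_genome_set` — reference genomes and divergent "unknown"
  relatives evolved by i.i.d. substitutions (no indels), with an exact
  pairwise-divergence truth table obtained by path addition on the
  genealogy.
* :func:`fragment_to_contigs` — non-overlapping contigs with log-normal
  depth-of-coverage noise, standing in for an assembler's output.
* :func:`simulate_cohort` — paired left/right, diseased/unaffected
  genus-abundance profiles with strong subject individuality and a
  planted disease effect on one taxon (the *Staphylococcus*-style
  increase the paired test must recover).
* :func:`simulate_mlst_reads` — short reads from housekeeping-locus
  alleles with i.i.d. substitution errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import Contig

__all__ = [
    "GenomeSpec",
    "CohortSpec",
    "DEFAULT_SKIN_PROFILE",
    "random_genome",
    "mutate",
    "evolve_genome_set",
    "fragment_to_contigs",
    "gene_windows",
    "simulate_cohort",
    "simulate_mlst_reads",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Genus-level base composition of a sebaceous-skin community.  Values are
# round numbers shaped after the dominant genera of human skin; the effect
# taxon is kept minor so that renormalisation spillover onto the other
# genera stays well below the per-sample noise.
DEFAULT_SKIN_PROFILE: dict[str, float] = {
    "Propionibacterium": 0.40,
    "Corynebacterium": 0.18,
    "Malassezia": 0.15,
    "Micrococcus": 0.12,
    "Staphylococcus": 0.05,
    "Streptococcus": 0.05,
    "Anaerococcus": 0.03,
    "Finegoldia": 0.02,
}


@dataclass
class GenomeSpec:
    """Specification of one genome on a substitution-only genealogy."""

    id: str
    length: int = 100_000
    gc_target: float = 0.5
    divergence_from_parent: float = 0.0
    parent: str | None = None  # None -> child of the ancestor

    def __post_init__(self) -> None:
        if self.length < 1000:
            raise ValueError(f"genome {self.id}: length must be >= 1000")
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError(f"genome {self.id}: gc_target must lie in (0, 1)")
        if not 0.0 <= self.divergence_from_parent < 0.5:
            raise ValueError(
                f"genome {self.id}: divergence_from_parent must lie in [0, 0.5)"
            )


@dataclass
class CohortSpec:
    """Study design for a paired-site abundance cohort.

    Each patient contributes left and right samples at every site; for
    each site one side carries psoriatic plaques and the contralateral
    side is unaffected, so every patient keeps at least one unaffected
    site.  ``subject_sd`` is the s.d. of the per-patient log-abundance
    offset shared by all of that patient's samples (subject
    individuality); ``sample_sd`` is an independent per-sample
    log-abundance dispersion emulating ecological noise between
    contralateral sites.  ``effect_multiplier`` scales ``effect_taxon``
    at diseased sites before renormalisation.
    """

    n_patients: int = 20
    sites: tuple[str, ...] = ("ear", "elbow")
    effect_taxon: str = "Staphylococcus"
    effect_multiplier: float = 2.0
    subject_sd: float = 1.0
    sample_sd: float = 0.35
    depth_per_sample: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.effect_multiplier < 1.0:
            raise ValueError("effect_multiplier must be >= 1")
        if self.subject_sd < 0 or self.sample_sd < 0:
            raise ValueError("dispersions must be non-negative")
        if self.depth_per_sample < 1:
            raise ValueError("depth_per_sample must be >= 1")
        if not self.sites:
            raise ValueError("at least one site is required")


def random_genome(length: int, gc_target: float, rng: np.random.Generator) -> str:
    """Random A/C/G/T sequence with expected GC ``gc_target``."""
    p = np.array(
        [(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2]
    )
    draws = rng.choice(4, size=length, p=p)
    return _BASES[draws].tobytes().decode("ascii")


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. substitutions at the given per-site rate (no indels)."""
    if rate == 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    idx = np.nonzero(hit)[0]
    if idx.size:
        # substitute with one of the three other bases, uniformly
        cur = arr[idx]
        offsets = rng.integers(1, 4, size=idx.size)
        codes = np.searchsorted(_BASES, cur)  # _BASES is sorted (A<C<G<T)
        arr[idx] = _BASES[(codes + offsets) % 4]
    return arr.tobytes().decode("ascii")


def evolve_genome_set(
    ancestor: GenomeSpec,
    children: list[GenomeSpec],
    seed: int,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Evolve a genome collection along a genealogy.

    ``children`` are processed in order; each entry's ``parent`` must be
    the ancestor (``None``) or an earlier child, which permits arbitrary
    planted tree topologies.  Returns the sequences and a symmetric truth
    table of expected pairwise divergence (path addition of the per-edge
    substitution rates).
    """
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    parent_of: dict[str, str | None] = {ancestor.id: None}
    edge_rate: dict[str, float] = {ancestor.id: 0.0}

    seqs[ancestor.id] = random_genome(ancestor.length, ancestor.gc_target, rng)
    for child in children:
        pid = child.parent if child.parent is not None else ancestor.id
        if pid not in seqs:
            raise ValueError(f"genome {child.id}: parent {pid!r} not yet generated")
        if child.id in seqs:
            raise ValueError(f"duplicate genome id {child.id!r}")
        seqs[child.id] = mutate(seqs[pid], child.divergence_from_parent, rng)
        parent_of[child.id] = pid
        edge_rate[child.id] = child.divergence_from_parent

    def root_path(node: str) -> dict[str, float]:
        """Cumulative divergence from ``node`` to each of its ancestors."""
        out = {node: 0.0}
        total = 0.0
        cur = node
        while parent_of[cur] is not None:
            total += edge_rate[cur]
            cur = parent_of[cur]  # type: ignore[assignment]
            out[cur] = total
        return out

    ids = list(seqs)
    paths = {g: root_path(g) for g in ids}
    mat = np.zeros((len(ids), len(ids)))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids[i + 1 :], start=i + 1):
            shared = [n for n in paths[a] if n in paths[b]]
            d = min(paths[a][n] + paths[b][n] for n in shared)
            mat[i, j] = mat[j, i] = d
    truth = pd.DataFrame(mat, index=ids, columns=ids)
    return seqs, truth


def fragment_to_contigs(
    genome: str,
    n_contigs: int,
    coverage_mean: float,
    coverage_cv: float,
    min_len: int,
    seed: int,
    source: str = "genome",
    id_prefix: str | None = None,
) -> list[Contig]:
    """Cut a genome into non-overlapping contigs covering it completely.

    Contig lengths are ``min_len`` plus a multinomially distributed share
    of the remainder; per-contig depth of coverage is log-normal around
    ``coverage_mean`` with coefficient of variation ``coverage_cv``.
    """
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if n_contigs * min_len > len(genome):
        raise ValueError(
            f"cannot cut {len(genome)} bases into {n_contigs} contigs of >= {min_len}"
        )
    rng = np.random.default_rng(seed)
    extra = len(genome) - n_contigs * min_len
    lengths = np.full(n_contigs, min_len, dtype=np.int64)
    if extra > 0:
        lengths += rng.multinomial(extra, np.full(n_contigs, 1.0 / n_contigs))
    if coverage_cv == 0.0:
        covs = np.full(n_contigs, float(coverage_mean))
    else:
        sigma2 = np.log1p(coverage_cv**2)
        mu = np.log(coverage_mean) - sigma2 / 2.0
        covs = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n_contigs)
    prefix = id_prefix if id_prefix is not None else source
    contigs = []
    pos = 0
    for i, (ln, cov) in enumerate(zip(lengths, covs)):
        contigs.append(
            Contig(
                id=f"{prefix}_c{i:03d}",
                seq=genome[pos : pos + int(ln)],
                coverage=float(cov),
                source=source,
            )
        )
        pos += int(ln)
    return contigs


def gene_windows(
    genome: str, n_genes: int, gene_len: int = 800, spacing: int = 200, id_prefix: str = "gene"
) -> dict[str, str]:
    """Annotate evenly spaced windows of a genome as a reference gene set.

    Used as the ortholog-search query set for core-genome runs on
    synthetic genomes (the windows play the role of an annotated
    reference gene catalogue).
    """
    step = gene_len + spacing
    if n_genes * step > len(genome):
        raise ValueError("gene windows exceed genome length")
    return {
        f"{id_prefix}{i:03d}": genome[i * step : i * step + gene_len]
        for i in range(n_genes)
    }


def simulate_cohort(
    spec: CohortSpec,
    taxon_base_profile: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a paired-site cohort of taxon read-count profiles.

    Returns ``(counts, metadata, truth)``:

    * ``counts`` — samples x taxa read counts; every row sums to
      ``depth_per_sample`` exactly (multinomial draws).
    * ``metadata`` — sample_id, patient, site, side, disease_state,
      antibiotic_flag.
    * ``truth`` — the per-sample multiplier applied to the effect taxon.
    """
    base = dict(taxon_base_profile) if taxon_base_profile else dict(DEFAULT_SKIN_PROFILE)
    total = sum(base.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"base profile must sum to 1 (got {total:.6g})")
    taxa = list(base)
    if spec.effect_taxon not in base and spec.effect_multiplier != 1.0:
        raise ValueError(f"effect taxon {spec.effect_taxon!r} absent from base profile")
    base_vec = np.array([base[t] for t in taxa])
    rng = np.random.default_rng(spec.seed)

    rows, meta_rows, truth_rows = [], [], []
    for p in range(1, spec.n_patients + 1):
        patient = f"P{p:02d}"
        offset = rng.normal(0.0, spec.subject_sd, size=len(taxa))
        for site in spec.sites:
            diseased_side = "left" if rng.random() < 0.5 else "right"
            for side in ("left", "right"):
                diseased = side == diseased_side
                sample_noise = (
                    rng.normal(0.0, spec.sample_sd, size=len(taxa))
                    if spec.sample_sd > 0
                    else np.zeros(len(taxa))
                )
                weights = base_vec * np.exp(offset + sample_noise)
                mult = 1.0
                if diseased and spec.effect_multiplier != 1.0:
                    mult = spec.effect_multiplier
                    weights[taxa.index(spec.effect_taxon)] *= mult
                probs = weights / weights.sum()
                counts = rng.multinomial(spec.depth_per_sample, probs)
                sid = f"{patient}_{site}_{side}"
                rows.append(pd.Series(counts, index=taxa, name=sid))
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "patient": patient,
                        "site": site,
                        "side": side,
                        "disease_state": "diseased" if diseased else "unaffected",
                        "antibiotic_flag": False,
                    }
                )
                truth_rows.append(
                    {"sample_id": sid, "effect_taxon": spec.effect_taxon, "multiplier": mult}
                )
    counts = pd.DataFrame(rows)
    counts.index.name = "sample_id"
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = pd.DataFrame(truth_rows).set_index("sample_id")
    return counts, metadata, truth


def simulate_mlst_reads(
    alleles: dict[str, str],
    read_len: int = 100,
    coverage: float = 20.0,
    error_rate: float = 0.01,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Shotgun-style reads over one true allele per locus.

    Each allele is embedded in random flanking sequence of one read
    length per side (housekeeping loci sit in genomic context, so real
    shotgun coverage does not taper at locus boundaries); reads are
    uniform substrings of the flanked sequence with i.i.d. substitution
    errors, and the read count is chosen so the mean depth over locus
    positions stays within 20% of ``coverage``.  Returns
    ``(reads, truth)`` where reads are ``(read_id, sequence)`` and truth
    maps read ids to their locus, their start relative to the locus, and
    the true allele sequence.
    """
    if not 0.0 <= error_rate <= 0.1:
        raise ValueError("error_rate must lie in [0, 0.1]")
    if read_len > min(len(s) for s in alleles.values()):
        raise ValueError("read_len exceeds the shortest allele")
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    truth_rows = []
    i = 0
    for locus, allele in alleles.items():
        flank_left = random_genome(read_len, 0.5, rng)
        flank_right = random_genome(read_len, 0.5, rng)
        template = flank_left + allele + flank_right
        n_starts = len(template) - read_len + 1
        # interior locus positions are covered by read_len of the n_starts
        # equally likely starts, so this read count realises `coverage`
        n_reads = max(1, round(coverage * n_starts / read_len))
        starts = rng.integers(0, n_starts, size=n_reads)
        for s in np.sort(starts):
            read = mutate(template[int(s) : int(s) + read_len], error_rate, rng)
            rid = f"r{i:05d}"
            reads.append((rid, read))
            truth_rows.append(
                {
                    "read_id": rid,
                    "locus": locus,
                    "start": int(s) - read_len,  # relative to the locus
                    "true_allele": allele,
                }
            )
            i += 1
    truth = pd.DataFrame(truth_rows).set_index("read_id")
    return reads, truth
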