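"""Core-genome concatenated alignment and neighbor-joining placement.

A reference gene catalogue is searched against every genome/bin with the
native aligner; hits longer than 500 bp at strictly more than 70%
identity count as plausible orthologs, genes present in strictly more
than 95% of the genomes form the core, and the per-genome gene blocks
are concatenated into one alignment (substitution-only data aligns
ungapped; a genome missing a near-core gene contributes an all-gap
block).  Columns above a fixed gap fraction are trimmed and the tree is
built by neighbor joining on p- or Jukes-Cantor distances with pairwise
gap deletion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.calculate import treecompare
from skbio import DistanceMatrix
from skbio.tree import nj

from .align import SubjectIndex, align_to_index
from .seqio import AlignmentHit

__all__ = [
    "OrthologHit",
    "OrthologTable",
    "ConcatAlignment",
    "find_orthologs",
    "select_core",
    "build_concat_alignment",
    "trim_alignment",
    "pairwise_distances",
    "nj_tree",
    "rf_distance",
]

MIN_ORTHOLOG_LEN = 500
MIN_ORTHOLOG_IDENTITY = 0.70
MIN_CORE_PREVALENCE = 0.95
MAX_GAP_FRACTION = 0.2
ORTHOLOG_SEED_K = 11  # shorter seed than contig mapping: genes may be distant

GAP = "-"


@dataclass
class OrthologHit:
    gene_id: str
    genome_id: str
    sequence: str  # genome block co-linear with the full gene (may carry gaps)
    identity: float
    aligned_length: int


class OrthologTable:
    """gene x genome matrix of accepted best hits."""

    def __init__(self, gene_ids: list[str], genome_ids: list[str]):
        self.gene_ids = list(gene_ids)
        self.genome_ids = list(genome_ids)
        self.hits: dict[tuple[str, str], OrthologHit] = {}

    def add(self, hit: OrthologHit) -> None:
        self.hits[(hit.gene_id, hit.genome_id)] = hit

    def get(self, gene_id: str, genome_id: str) -> OrthologHit | None:
        return self.hits.get((gene_id, genome_id))

    def prevalence(self, gene_id: str) -> float:
        n = sum(1 for g in self.genome_ids if (gene_id, g) in self.hits)
        return n / len(self.genome_ids)


@dataclass
class ConcatAlignment:
    genome_ids: list[str]
    rows: dict[str, str]  # genome id -> aligned sequence
    block_bounds: list[tuple[str, int, int]]  # (gene, start, end) half-open columns

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def column_gap_fraction(self) -> np.ndarray:
        mat = np.array([list(self.rows[g]) for g in self.genome_ids])
        return (mat == GAP).mean(axis=0)


def _extract_block(
    gene_seq: str, genome_seq: str, hit: AlignmentHit
) -> str:
    """Map the full gene interval onto the genome along the hit diagonal.

    For ungapped hits the genome block co-linear with gene positions
    [0, L) sits at [diag, diag + L); positions falling off the genome
    ends become gap characters so every block has the gene's length.
    """
    diag = hit.subject_start - hit.query_start
    L = len(gene_seq)
    start, end = diag, diag + L
    left_pad = max(0, -start)
    right_pad = max(0, end - len(genome_seq))
    core = genome_seq[max(0, start) : min(len(genome_seq), end)]
    return GAP * left_pad + core + GAP * right_pad


def find_orthologs(
    reference_genes: dict[str, str],
    genomes: dict[str, str],
    min_len: int = MIN_ORTHOLOG_LEN,
    min_identity: float = MIN_ORTHOLOG_IDENTITY,
    k: int = ORTHOLOG_SEED_K,
) -> OrthologTable:
    """Best accepted hit of every reference gene in every genome.

    Acceptance is strict: aligned length > ``min_len`` and identity >
    ``min_identity``.  Multi-copy hits resolve to the best score (ties to
    the lowest subject coordinate, deterministically).
    """
    if not reference_genes:
        raise ValueError("reference gene set is empty")
    table = OrthologTable(list(reference_genes), list(genomes))
    for genome_id, genome_seq in genomes.items():
        index = SubjectIndex(genome_id, genome_seq, k=k)
        for gene_id, gene_seq in reference_genes.items():
            hits = align_to_index(
                gene_id,
                gene_seq,
                index,
                min_identity=min_identity,
                min_len=min_len + 1,
            )
            hits = [h for h in hits if h.aligned_length > min_len and h.identity > min_identity]
            if not hits:
                continue
            best = max(hits, key=lambda h: (h.score, -h.subject_start))
            table.add(
                OrthologHit(
                    gene_id=gene_id,
                    genome_id=genome_id,
                    sequence=_extract_block(gene_seq, genome_seq, best),
                    identity=best.identity,
                    aligned_length=best.aligned_length,
                )
            )
    return table


def select_core(table: OrthologTable, min_prevalence: float = MIN_CORE_PREVALENCE) -> list[str]:
    """Genes present in strictly more than ``min_prevalence`` of genomes.

    Gene order is the stable input order; an empty core is an error
    because no tree can be built from it.
    """
    core = [g for g in table.gene_ids if table.prevalence(g) > min_prevalence]
    if not core:
        raise ValueError(
            f"no gene exceeds prevalence {min_prevalence:.2f}: core genome is empty"
        )
    return core


def build_concat_alignment(
    core_genes: list[str],
    table: OrthologTable,
    reference_genes: dict[str, str],
) -> ConcatAlignment:
    """Concatenate per-gene blocks in stable gene order.

    Genomes lacking an accepted hit for a core gene contribute an all-gap
    block of that gene's length.
    """
    if not core_genes:
        raise ValueError("core gene list is empty")
    rows = {g: [] for g in table.genome_ids}
    bounds = []
    col = 0
    for gene in core_genes:
        L = len(reference_genes[gene])
        for genome in table.genome_ids:
            hit = table.get(gene, genome)
            rows[genome].append(hit.sequence if hit is not None else GAP * L)
        bounds.append((gene, col, col + L))
        col += L
    return ConcatAlignment(
        genome_ids=list(table.genome_ids),
        rows={g: "".join(parts) for g, parts in rows.items()},
        block_bounds=bounds,
    )


def trim_alignment(
    aln: ConcatAlignment, max_gap_fraction: float = MAX_GAP_FRACTION
) -> ConcatAlignment:
    """Drop columns whose gap fraction exceeds ``max_gap_fraction``."""
    gap_frac = aln.column_gap_fraction()
    keep = gap_frac <= max_gap_fraction
    if not keep.any():
        raise ValueError("trimming removed every column of the alignment")
    mat = np.array([list(aln.rows[g]) for g in aln.genome_ids])
    trimmed = mat[:, keep]
    # remap block boundaries onto the surviving columns
    kept_cum = np.concatenate(([0], np.cumsum(keep)))
    bounds = []
    for gene, start, end in aln.block_bounds:
        s, e = int(kept_cum[start]), int(kept_cum[end])
        if e > s:
            bounds.append((gene, s, e))
    return ConcatAlignment(
        genome_ids=list(aln.genome_ids),
        rows={g: "".join(trimmed[i]) for i, g in enumerate(aln.genome_ids)},
        block_bounds=bounds,
    )


def pairwise_distances(aln: ConcatAlignment, model: str = "jc") -> pd.DataFrame:
    """Pairwise distances with pairwise deletion of gap sites.

    ``model`` is "p" (raw mismatch fraction) or "jc" (Jukes-Cantor,
    d = -3/4 ln(1 - 4p/3), undefined at p >= 0.75).
    """
    if model not in {"p", "jc"}:
        raise ValueError("model must be 'p' or 'jc'")
    ids = aln.genome_ids
    mat = np.array([np.frombuffer(aln.rows[g].encode(), dtype=np.uint8) for g in ids])
    gap = ord(GAP)
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (mat[i] != gap) & (mat[j] != gap)
            sites = int(ok.sum())
            if sites == 0:
                raise ValueError(f"no shared ungapped site between {ids[i]} and {ids[j]}")
            p = float((mat[i][ok] != mat[j][ok]).mean())
            if model == "p":
                d = p
            else:
                if p >= 0.75:
                    raise ValueError(
                        f"Jukes-Cantor distance undefined for {ids[i]} vs {ids[j]} "
                        f"(mismatch fraction {p:.3f} >= 0.75)"
                    )
                d = -0.75 * np.log1p(-4.0 * p / 3.0)
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=ids, columns=ids)


def nj_tree(aln: ConcatAlignment, model: str = "jc") -> str:
    """Neighbor-joining tree (Newick) from the concatenated alignment.

    Deterministic under fixed input order; negative branch lengths are
    clamped to zero.
    """
    if len(aln.genome_ids) < 3:
        raise ValueError("neighbor joining needs at least 3 genomes")
    dm = pairwise_distances(aln, model=model)
    tree = nj(DistanceMatrix(dm.values, ids=dm.index.tolist()), neg_as_zero=True)
    return str(tree).strip()


def rf_distance(newick_a: str, newick_b: str) -> int:
    """Robinson-Foulds (bipartition symmetric-difference) distance."""
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    la = {t.label for t in ta.leaf_node_iter() for t in [t.taxon]}
    lb = {t.label for t in tb.leaf_node_iter() for t in [t.taxon]}
    if la != lb:
        raise ValueError(f"leaf sets differ: {sorted(la ^ lb)}")
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return int(treecompare.symmetric_difference(ta, tb))


def write_alignment_fasta(aln: ConcatAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in aln.genome_ids:
            fh.write(f">{g}\n")
            row = aln.rows[g]
            for i in range(0, len(row), 80):
                fh.write(row[i : i + 80] + "\n")


def write_core_genes(core: list[str], table: OrthologTable, path: str | Path) -> None:
    pd.DataFrame(
        [{"gene_id": g, "prevalence": f"{table.prevalence(g):.4f}"} for g in core]
    ).to_csv(path, sep="\t", index=False)
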