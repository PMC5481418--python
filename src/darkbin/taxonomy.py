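"""Conservative per-contig species assignment.

A contig receives a species label only when, against its single best
matching reference genome, both the breadth of coverage (fraction of the
contig covered by the union of alignment intervals) and the
length-weighted mean identity are strictly above 90%.  Everything else
stays "unassigned" and is handed to GC-coverage binning.  Thresholds are
strict on purpose: boundary equality is not enough for an assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .seqio import AlignmentHit, Contig

__all__ = [
    "UNASSIGNED",
    "ContigAssignment",
    "TaxonBin",
    "breadth_and_identity",
    "best_reference",
    "assign_contig",
    "assign_contigs",
    "bin_by_label",
    "write_assignments",
]

UNASSIGNED = "unassigned"

BREADTH_THRESHOLD = 0.90
IDENTITY_THRESHOLD = 0.90
MIN_BINNED_CONTIG_LEN = 1000


@dataclass
class ContigAssignment:
    contig_id: str
    best_reference: str | None
    breadth: float
    identity: float
    label: str


@dataclass
class TaxonBin:
    """A set of contigs grouped under one label or cluster."""

    bin_id: str
    contigs: list[Contig]
    status: str = "species-labelled"  # species-labelled | preliminary | curated | rejected

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.contigs)


def breadth_and_identity(
    contig_length: int, hits: list[AlignmentHit]
) -> tuple[float, float]:
    """Breadth of coverage and length-weighted identity vs one reference.

    Breadth is |union of query intervals| / contig_length; identity is
    the alignment-length-weighted mean of per-hit identities (overlap is
    counted once per hit).  No hits yields (0, 0).
    """
    if not hits:
        return 0.0, 0.0
    subjects = {h.subject_id for h in hits}
    if len(subjects) > 1:
        raise ValueError(f"hits span multiple subjects: {sorted(subjects)}")
    intervals = []
    for h in hits:
        if h.query_start < 0 or h.query_end > contig_length:
            raise ValueError(
                f"hit interval [{h.query_start}, {h.query_end}) outside contig of "
                f"length {contig_length}"
            )
        intervals.append((h.query_start, h.query_end))
    intervals.sort()
    covered = 0
    cur_start, cur_end = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_end:
            covered += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    covered += cur_end - cur_start
    total_len = sum(h.aligned_length for h in hits)
    identity = sum(h.identity * h.aligned_length for h in hits) / total_len
    return covered / contig_length, identity


def best_reference(hits: list[AlignmentHit]) -> str | None:
    """Reference maximising the summed identity-weighted aligned length.

    Ties break to the lexicographically smaller genome id; no hits give
    ``None``.
    """
    if not hits:
        return None
    scores: dict[str, float] = {}
    for h in hits:
        scores[h.subject_id] = scores.get(h.subject_id, 0.0) + h.score
    return min(scores, key=lambda g: (-scores[g], g))


def assign_contig(breadth: float, identity: float, species: str) -> str:
    """The 90/90 rule: a species label needs both margins strictly above 0.90."""
    if not (0.0 <= breadth <= 1.0 and 0.0 <= identity <= 1.0):
        raise ValueError("breadth and identity must lie in [0, 1]")
    if breadth > BREADTH_THRESHOLD and identity > IDENTITY_THRESHOLD:
        return species
    return UNASSIGNED


def assign_contigs(
    contigs: list[Contig],
    hits: list[AlignmentHit],
    reference_species: dict[str, str],
) -> list[ContigAssignment]:
    """Assign every contig against its best-matching reference genome.

    ``reference_species`` maps reference genome ids to species names
    (user-supplied metadata standing in for a curated reference
    database).
    """
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    out = []
    for c in contigs:
        chits = by_query.get(c.id, [])
        ref = best_reference(chits)
        if ref is None:
            out.append(ContigAssignment(c.id, None, 0.0, 0.0, UNASSIGNED))
            continue
        ref_hits = [h for h in chits if h.subject_id == ref]
        breadth, identity = breadth_and_identity(c.length, ref_hits)
        species = reference_species.get(ref)
        if species is None:
            label = UNASSIGNED
        else:
            label = assign_contig(breadth, identity, species)
        out.append(ContigAssignment(c.id, ref, breadth, identity, label))
    return out


def bin_by_label(
    assignments: list[ContigAssignment],
    contigs: list[Contig],
    min_contig_len: int = MIN_BINNED_CONTIG_LEN,
) -> tuple[dict[str, TaxonBin], list[Contig]]:
    """Group labelled long contigs (> ``min_contig_len``) into species bins.

    Unassigned or short contigs form the residual set passed on to
    GC-coverage binning.  Every input contig lands in exactly one output
    set.
    """
    label_of = {a.contig_id: a.label for a in assignments}
    bins: dict[str, TaxonBin] = {}
    residual: list[Contig] = []
    for c in contigs:
        label = label_of.get(c.id, UNASSIGNED)
        if label != UNASSIGNED and c.length > min_contig_len:
            bins.setdefault(label, TaxonBin(bin_id=label, contigs=[])).contigs.append(c)
        else:
            residual.append(c)
    return bins, residual


def write_assignments(assignments: list[ContigAssignment], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "contig_id": a.contig_id,
                "best_reference": a.best_reference if a.best_reference else "NA",
                "breadth": f"{a.breadth:.6f}",
                "identity": f"{a.identity:.6f}",
                "label": a.label,
            }
            for a in assignments
        ]
    ).to_csv(path, sep="\t", index=False)
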