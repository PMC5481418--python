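"""Deterministic seed-and-extend ungapped local aligner.

Desk-scale nucleotide aligner used to map contigs, ANI fragments and
core-genome genes onto reference sequences.  Exact k-mer seeds define
candidate diagonals; on each seeded diagonal the maximal-scoring ungapped
segment (match +1, mismatch -2) is reported as a hit.  Because the
synthetic genomes evolve by substitutions only, ungapped alignment is
exact for them; gapped hits produced by external mappers enter the
pipeline through :func:`darkbin.seqio.read_hit_table` instead.
"""

from __future__ import annotations

import numpy as np

from .seqio import AlignmentHit

__all__ = ["SubjectIndex", "seed_extend_align", "revcomp"]

# defaults chosen below every downstream threshold (90/90 assignment,
# 70% ANI fragment retention) so the aligner never pre-empts a rule
DEFAULT_K = 15
DEFAULT_MIN_IDENTITY = 0.70
DEFAULT_MIN_LEN = 100

_MATCH = 1
_MISMATCH = -2

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class SubjectIndex:
    """Exact k-mer index of one subject sequence.

    Building the index once and streaming many queries against it is the
    fast path for fragment ANI and ortholog search.
    """

    def __init__(self, subject_id: str, seq: str, k: int = DEFAULT_K):
        if k < 8:
            raise ValueError("seed length k must be >= 8")
        self.subject_id = subject_id
        self.seq = seq
        self.k = k
        self.arr = _encode(seq)
        index: dict[str, list[int]] = {}
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append(pos)
        self._index = index

    def seed_diagonals(self, query: str) -> list[int]:
        """Sorted diagonals (subject_pos - query_pos) hit by exact seeds."""
        k = self.k
        diags: set[int] = set()
        idx = self._index
        for qpos in range(len(query) - k + 1):
            positions = idx.get(query[qpos : qpos + k])
            if positions:
                for spos in positions:
                    diags.add(spos - qpos)
        return sorted(diags)


def _best_segment(vals: np.ndarray) -> tuple[int, int, int] | None:
    """Maximal-sum contiguous segment (Kadane, vectorised).

    Returns (start, end, n_matches) in local coordinates, or None when no
    positive-scoring segment exists.  First-occurrence argmax/argmin keep
    the result deterministic.
    """
    prefix = np.concatenate(([0], np.cumsum(vals)))
    run_min = np.minimum.accumulate(prefix[:-1])
    gains = prefix[1:] - run_min
    end = int(np.argmax(gains))
    if gains[end] <= 0:
        return None
    start = int(np.argmin(prefix[: end + 1]))
    seg = vals[start : end + 1]
    n_match = int(np.count_nonzero(seg == _MATCH))
    return start, end + 1, n_match


def _align_diagonal(
    qarr: np.ndarray, index: SubjectIndex, diag: int
) -> tuple[int, int, int] | None:
    """Best ungapped segment on one diagonal.

    Returns (query_start, query_end, n_matches) or None.
    """
    q0 = max(0, -diag)
    q1 = min(len(qarr), len(index.arr) - diag)
    if q1 - q0 <= 0:
        return None
    eq = qarr[q0:q1] == index.arr[q0 + diag : q1 + diag]
    vals = np.where(eq, _MATCH, _MISMATCH).astype(np.int64)
    seg = _best_segment(vals)
    if seg is None:
        return None
    s, e, m = seg
    return q0 + s, q0 + e, m


def align_to_index(
    query_id: str,
    query: str,
    index: SubjectIndex,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_len: int = DEFAULT_MIN_LEN,
    search_rc: bool = False,
) -> list[AlignmentHit]:
    """Align one query against a pre-built subject index."""
    hits: list[AlignmentHit] = []
    strands = [(query, False)]
    if search_rc:
        strands.append((revcomp(query), True))
    for qseq, minus in strands:
        if len(qseq) < index.k:
            continue
        qarr = _encode(qseq)
        for diag in index.seed_diagonals(qseq):
            seg = _align_diagonal(qarr, index, diag)
            if seg is None:
                continue
            qs, qe, n_match = seg
            length = qe - qs
            identity = n_match / length
            if length < min_len or identity < min_identity:
                continue
            if minus:
                # report the interval on the forward query
                fs, fe = len(qseq) - qe, len(qseq) - qs
            else:
                fs, fe = qs, qe
            hits.append(
                AlignmentHit(
                    query_id=query_id,
                    subject_id=index.subject_id,
                    query_start=fs,
                    query_end=fe,
                    subject_start=qs + diag,
                    subject_end=qe + diag,
                    identity=identity,
                    aligned_length=length,
                    minus_strand=minus,
                    mismatches=length - n_match,
                    gap_opens=0,
                    bitscore=float(n_match * _MATCH + (length - n_match) * _MISMATCH),
                )
            )
    # overlapping same-diagonal segments cannot occur (one segment per
    # diagonal), so sorting is the only merge step needed
    hits.sort(key=lambda h: (h.query_id, h.query_start, h.subject_id, h.subject_start))
    return _dedupe(hits)


def _dedupe(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    seen = set()
    out = []
    for h in hits:
        key = (h.query_id, h.subject_id, h.query_start, h.query_end, h.subject_start, h.minus_strand)
        if key not in seen:
            seen.add(key)
            out.append(h)
    return out


def seed_extend_align(
    query: str,
    subject: str,
    k: int = DEFAULT_K,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_len: int = DEFAULT_MIN_LEN,
    query_id: str = "query",
    subject_id: str = "subject",
    search_rc: bool = False,
) -> list[AlignmentHit]:
    """Align two raw sequences; empty input yields an empty hit list."""
    if not query or not subject or len(subject) < k:
        return []
    index = SubjectIndex(subject_id, subject, k=k)
    return align_to_index(
        query_id, query, index, min_identity=min_identity, min_len=min_len, search_rc=search_rc
    )
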