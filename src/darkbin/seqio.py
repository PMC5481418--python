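"""Sequence and alignment-hit I/O.

FASTA handling is delegated to Biopython; contig headers may carry
``key=value`` tokens (``cov=<float> src=<id>``) which are parsed into
:class:`Contig` records.  Alignment hits use the 12-column BLAST tabular
dialect (qseqid sseqid pident length mismatch gapopen qstart qend sstart
send evalue bitscore) with 1-based inclusive coordinates on disk and
0-based half-open coordinates in memory.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Contig",
    "AlignmentHit",
    "HitTableError",
    "read_fasta",
    "write_fasta",
    "read_contigs",
    "write_contigs",
    "read_hit_table",
    "write_hit_table",
    "gc_fraction",
]

_UNAMBIGUOUS = set("ACGT")


def gc_fraction(seq: str) -> float:
    """(#G + #C) / (#A + #C + #G + #T), ignoring ambiguous bases.

    Raises ``ValueError`` when the sequence has no unambiguous base.
    """
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("sequence contains no unambiguous A/C/G/T base")
    return gc / (gc + at)


@dataclass
class Contig:
    """An assembled sequence with depth-of-coverage and optional truth label."""

    id: str
    seq: str
    coverage: float = 0.0
    source: str | None = None  # true genome of origin, when known

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def gc(self) -> float:
        return gc_fraction(self.seq)


@dataclass
class AlignmentHit:
    """Ungapped (native) or gapped (external) local alignment of a query
    interval onto a subject interval.

    Coordinates are 0-based half-open.  ``identity`` is a fraction in
    [0, 1]; ``aligned_length`` is the alignment length as reported by the
    producer (equal to ``query_end - query_start`` for native hits).
    """

    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    identity: float
    aligned_length: int
    minus_strand: bool = False
    mismatches: int = 0
    gap_opens: int = 0
    evalue: float = 0.0
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if self.query_end <= self.query_start:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: query_end must exceed query_start"
            )
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must lie in [0, 1]")

    @property
    def score(self) -> float:
        """Aggregation score used for best-reference choices."""
        return self.identity * self.aligned_length


class HitTableError(ValueError):
    """Malformed row in a tabular hit file (carries the line number)."""


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = records.items() if isinstance(records, dict) else records
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(recs)


def write_contigs(contigs: Sequence[Contig], path: str | Path) -> None:
    """Write contigs with ``cov=`` / ``src=`` header tokens."""
    recs = []
    for c in contigs:
        desc = f"cov={c.coverage:.6g}"
        if c.source is not None:
            desc += f" src={c.source}"
        recs.append(SeqRecord(Seq(c.seq), id=c.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(recs)


def read_contigs(path: str | Path) -> list[Contig]:
    """Read a contig FASTA, parsing ``cov=``/``src=`` tokens from headers."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        cov = 0.0
        src = None
        for tok in rec.description.split()[1:]:
            if tok.startswith("cov="):
                cov = float(tok[4:])
            elif tok.startswith("src="):
                src = tok[4:]
        out.append(Contig(id=rec.id, seq=str(rec.seq).upper(), coverage=cov, source=src))
    return out


def _hit_from_row(fields: list[str], lineno: int) -> AlignmentHit:
    if len(fields) != 12:
        raise HitTableError(f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}")
    try:
        qid, sid = fields[0], fields[1]
        pident = float(fields[2])
        length = int(fields[3])
        mism = int(fields[4])
        gapo = int(fields[5])
        qs, qe, ss, se = (int(fields[i]) for i in range(6, 10))
        evalue = float(fields[10])
        bits = float(fields[11])
    except ValueError as exc:
        raise HitTableError(f"line {lineno}: {exc}") from exc
    identity = pident / 100.0
    # Ungapped rows carry an exact match count; prefer it over the rounded
    # percent-identity column so that write -> read round-trips losslessly.
    if gapo == 0 and length > 0:
        exact = (length - mism) / length
        if abs(exact - identity) <= 0.005:
            identity = exact
    minus = False
    if qs > qe:
        qs, qe = qe, qs
        minus = not minus
    if ss > se:
        ss, se = se, ss
        minus = not minus
    return AlignmentHit(
        query_id=qid,
        subject_id=sid,
        query_start=qs - 1,
        query_end=qe,
        subject_start=ss - 1,
        subject_end=se,
        identity=identity,
        aligned_length=length,
        minus_strand=minus,
        mismatches=mism,
        gap_opens=gapo,
        evalue=evalue,
        bitscore=bits,
    )


def read_hit_table(path: str | Path) -> list[AlignmentHit]:
    """Parse a 12-column BLAST tabular file into alignment hits.

    Rows with descending coordinates (minus-strand hits) are normalised to
    ascending intervals with ``minus_strand`` set.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            hits.append(_hit_from_row(line.split("\t"), lineno))
    return hits


def write_hit_table(hits: Sequence[AlignmentHit], path: str | Path) -> None:
    """Write hits in the 12-column tabular dialect (1-based inclusive)."""
    with open(path, "w") as fh:
        for h in hits:
            ss, se = h.subject_start + 1, h.subject_end
            if h.minus_strand:
                ss, se = se, ss
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.identity * 100.0:.2f}",
                        str(h.aligned_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.query_start + 1),
                        str(h.query_end),
                        str(ss),
                        str(se),
                        f"{h.evalue:.2g}",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )
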