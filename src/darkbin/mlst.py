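"""Metagenomic multi-locus sequence typing.

Reads are anchored to scheme loci by exact k-mer matches (k = 21) against
the catalogued alleles, stacked into per-position pileups, and collapsed
into a consensus allele per locus: majority base where more than one read
covers a position (ties fall back to the template), the observed base at
single coverage, and the template base at zero coverage.  The template is
the catalogued allele closest (minimum Hamming distance) to a preliminary
majority sequence.  Consensus alleles are matched to the catalogue by
exact equality, the sequence type is looked up in the profile table, and
two samples carry the identical strain when at most one locus differs and
no differing locus differs by more than one SNP.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import read_fasta

__all__ = [
    "Scheme",
    "LocusPileup",
    "MLSTProfile",
    "make_scheme",
    "pileup_reads",
    "consensus_allele",
    "assign_st",
    "strains_identical",
    "hamming",
]

ANCHOR_K = 21

ST_NOVEL = "novel"
ST_INCOMPLETE = "incomplete"

_BASE_TO_COL = {"A": 0, "C": 1, "G": 2, "T": 3}
_COL_TO_BASE = "ACGT"


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("Hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class Scheme:
    """An MLST scheme: ordered loci, catalogued alleles, ST profile table.

    ``alleles[locus][allele_id]`` is the allele sequence; all alleles of
    one locus share one length (substitution-only variation).
    ``profiles`` maps an ST number to its per-locus allele ids.
    """

    loci: list[str]
    alleles: dict[str, dict[int, str]]
    profiles: pd.DataFrame  # index: ST (int); columns: loci; values: allele ids

    def __post_init__(self) -> None:
        for locus in self.loci:
            lens = {len(s) for s in self.alleles[locus].values()}
            if len(lens) != 1:
                raise ValueError(f"locus {locus}: alleles have unequal lengths")

    def locus_length(self, locus: str) -> int:
        return len(next(iter(self.alleles[locus].values())))

    @classmethod
    def from_directory(cls, path: str | Path) -> "Scheme":
        """Load a PubMLST-style scheme directory.

        Expects one ``<locus>.fasta`` per locus with headers
        ``<locus>_<allele_id>`` and a ``profiles.tsv`` with columns
        ``ST`` then one per locus.
        """
        path = Path(path)
        profiles = pd.read_csv(path / "profiles.tsv", sep="\t").set_index("ST")
        loci = list(profiles.columns)
        alleles: dict[str, dict[int, str]] = {}
        for locus in loci:
            fa = read_fasta(path / f"{locus}.fasta")
            alleles[locus] = {
                int(name.rsplit("_", 1)[1]): seq for name, seq in fa.items()
            }
        return cls(loci=loci, alleles=alleles, profiles=profiles)

    def to_directory(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.profiles.reset_index().to_csv(path / "profiles.tsv", sep="\t", index=False)
        for locus in self.loci:
            with open(path / f"{locus}.fasta", "w") as fh:
                for aid in sorted(self.alleles[locus]):
                    fh.write(f">{locus}_{aid}\n{self.alleles[locus][aid]}\n")


@dataclass
class LocusPileup:
    locus_id: str
    template: str
    counts: np.ndarray  # positions x 4 (A, C, G, T)

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.template), 4):
            raise ValueError("pileup counts must be (template length, 4)")


@dataclass
class MLSTProfile:
    sample_id: str
    scheme_loci: list[str]
    allele_ids: dict[str, int | str]  # allele number or "new"
    allele_seqs: dict[str, str | None]  # None when the locus had no reads
    st: int | str  # ST number, "novel", or "incomplete"


def make_scheme(
    n_loci: int = 8,
    locus_len: int = 450,
    n_alleles: int = 5,
    n_sts: int = 6,
    seed: int = 0,
) -> Scheme:
    """Generate a synthetic PubMLST-style scheme with known structure.

    Allele 1 of each locus is a random sequence; further alleles differ
    from it by 1..4 substitutions.  ST 1 is all-allele-1; the remaining
    STs are random combinations.
    """
    from .simulate import mutate, random_genome  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    loci = [f"locus{i + 1}" for i in range(n_loci)]
    alleles: dict[str, dict[int, str]] = {}
    for locus in loci:
        base = random_genome(locus_len, 0.5, rng)
        allele_set = {1: base}
        seen = {base}
        aid = 2
        while aid <= n_alleles:
            n_snps = int(rng.integers(1, 5))
            cand = list(base)
            for pos in rng.choice(locus_len, size=n_snps, replace=False):
                cur = cand[pos]
                options = [b for b in "ACGT" if b != cur]
                cand[pos] = options[int(rng.integers(0, 3))]
            cand_seq = "".join(cand)
            if cand_seq not in seen:
                seen.add(cand_seq)
                allele_set[aid] = cand_seq
                aid += 1
        alleles[locus] = allele_set
    rows = [{**{"ST": 1}, **{locus: 1 for locus in loci}}]
    seen_profiles = {tuple(1 for _ in loci)}
    st = 2
    while st <= n_sts:
        combo = tuple(int(a) for a in rng.integers(1, n_alleles + 1, size=n_loci))
        if combo not in seen_profiles:
            seen_profiles.add(combo)
            rows.append({**{"ST": st}, **dict(zip(loci, combo))})
            st += 1
    profiles = pd.DataFrame(rows).set_index("ST")
    return Scheme(loci=loci, alleles=alleles, profiles=profiles)


def _anchor_index(scheme: Scheme, k: int) -> dict[str, tuple[str, int]]:
    """k-mer -> (locus, offset) over all catalogued alleles.

    Within one locus the alleles are co-linear, so any allele provides
    valid locus coordinates.  k-mers mapping to more than one locus are
    dropped as ambiguous.
    """
    index: dict[str, tuple[str, int]] = {}
    ambiguous: set[str] = set()
    for locus in scheme.loci:
        for seq in scheme.alleles[locus].values():
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                prev = index.get(kmer)
                if prev is None:
                    index[kmer] = (locus, pos)
                elif prev[0] != locus:
                    ambiguous.add(kmer)
    for kmer in ambiguous:
        index.pop(kmer, None)
    return index


def pileup_reads(
    reads: list[tuple[str, str]], scheme: Scheme, k: int = ANCHOR_K
) -> dict[str, LocusPileup]:
    """Anchor reads to loci by exact k-mer match and build pileups.

    The first anchoring k-mer of a read fixes its locus and offset
    (substitution-only variation keeps all alleles of a locus
    co-linear).  The pileup template is filled in afterwards by
    :func:`consensus_allele` machinery via the closest catalogued allele.
    """
    index = _anchor_index(scheme, k)
    counts = {
        locus: np.zeros((scheme.locus_length(locus), 4), dtype=np.int64)
        for locus in scheme.loci
    }
    for _rid, seq in reads:
        placed = None
        for rpos in range(len(seq) - k + 1):
            entry = index.get(seq[rpos : rpos + k])
            if entry is not None:
                placed = (entry[0], entry[1] - rpos)
                break
        if placed is None:
            continue
        locus, offset = placed
        L = scheme.locus_length(locus)
        for i, base in enumerate(seq):
            pos = offset + i
            if 0 <= pos < L and base in _BASE_TO_COL:
                counts[locus][pos, _BASE_TO_COL[base]] += 1
    pileups = {}
    for locus in scheme.loci:
        template = _closest_template(counts[locus], scheme, locus)
        pileups[locus] = LocusPileup(locus_id=locus, template=template, counts=counts[locus])
    return pileups


def _closest_template(counts: np.ndarray, scheme: Scheme, locus: str) -> str:
    """Catalogued allele nearest to the preliminary majority sequence.

    Positions without coverage are ignored in the distance; ties break to
    the lowest allele id.
    """
    coverage = counts.sum(axis=1)
    maj = counts.argmax(axis=1)
    best_id = None
    best_dist = None
    for aid in sorted(scheme.alleles[locus]):
        seq = scheme.alleles[locus][aid]
        dist = sum(
            1
            for pos in range(len(seq))
            if coverage[pos] > 0 and _COL_TO_BASE[maj[pos]] != seq[pos]
        )
        if best_dist is None or dist < best_dist:
            best_id, best_dist = aid, dist
    return scheme.alleles[locus][best_id]


def consensus_allele(pileup: LocusPileup) -> str:
    """Collapse a pileup into a consensus sequence.

    Coverage >= 2: majority base, ties resolved to the template base;
    coverage 1: the observed base; coverage 0: the template base.
    """
    out = []
    for pos, template_base in enumerate(pileup.template):
        row = pileup.counts[pos]
        cov = int(row.sum())
        if cov == 0:
            out.append(template_base)
        elif cov == 1:
            out.append(_COL_TO_BASE[int(row.argmax())])
        else:
            top = int(row.max())
            winners = [b for b in range(4) if row[b] == top]
            if len(winners) == 1:
                out.append(_COL_TO_BASE[winners[0]])
            else:
                out.append(template_base)
    return "".join(out)


def assign_st(
    consensus: dict[str, str | None], scheme: Scheme, sample_id: str = "sample"
) -> MLSTProfile:
    """Match consensus alleles to the catalogue and look up the ST.

    A locus with no consensus (no reads) makes the profile incomplete; an
    allele absent from the catalogue is "new" and makes the type novel;
    a full set of known alleles whose combination is absent from the
    profile table is likewise reported as novel (an uncatalogued type).
    """
    unknown = set(consensus) - set(scheme.loci)
    if unknown:
        raise ValueError(f"loci not in scheme: {sorted(unknown)}")
    allele_ids: dict[str, int | str] = {}
    missing = False
    has_new = False
    for locus in scheme.loci:
        seq = consensus.get(locus)
        if seq is None:
            missing = True
            allele_ids[locus] = "missing"
            continue
        match = None
        for aid in sorted(scheme.alleles[locus]):
            if scheme.alleles[locus][aid] == seq:
                match = aid
                break
        if match is None:
            has_new = True
            allele_ids[locus] = "new"
        else:
            allele_ids[locus] = match
    if missing:
        st: int | str = ST_INCOMPLETE
    elif has_new:
        st = ST_NOVEL
    else:
        st = ST_NOVEL
        for st_num, row in scheme.profiles.iterrows():
            if all(int(row[locus]) == allele_ids[locus] for locus in scheme.loci):
                st = int(st_num)
                break
    return MLSTProfile(
        sample_id=sample_id,
        scheme_loci=list(scheme.loci),
        allele_ids=allele_ids,
        allele_seqs={locus: consensus.get(locus) for locus in scheme.loci},
        st=st,
    )


def strains_identical(
    profile_a: MLSTProfile, profile_b: MLSTProfile
) -> tuple[bool, dict[str, int]]:
    """Strain-identity rule for two typed samples.

    Identical iff at most one locus differs and no differing locus
    differs by more than one SNP.  (For the canonical 8-locus scheme this
    is exactly "more than six of eight loci identical"; the at-most-one
    differing locus form generalises it to schemes of any size.)  Returns
    the decision and per-locus SNP counts; loci missing in either profile
    make the comparison impossible.
    """
    if profile_a.scheme_loci != profile_b.scheme_loci:
        raise ValueError("profiles come from different schemes")
    snps: dict[str, int] = {}
    for locus in profile_a.scheme_loci:
        sa, sb = profile_a.allele_seqs[locus], profile_b.allele_seqs[locus]
        if sa is None or sb is None:
            raise ValueError(f"locus {locus} missing in one profile")
        snps[locus] = hamming(sa, sb)
    differing = [locus for locus, d in snps.items() if d > 0]
    identical = len(differing) <= 1 and all(snps[locus] <= 1 for locus in differing)
    return identical, snps


def write_profiles(profiles: list[MLSTProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        row = {"sample_id": p.sample_id, "ST": p.st}
        for locus in p.scheme_loci:
            row[locus] = p.allele_ids[locus]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
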