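"""Rarefaction, alpha/beta diversity and the paired-site abundance test.

The protocol mirrors a paired contralateral-site study design: samples
are rarefied to a common depth (50 k reads by default) before diversity
is computed; richness and the Gini-Simpson index summarise alpha
diversity; Bray-Curtis distances split into intra-subject vs
inter-subject distributions quantify subject individuality; and
disease-associated taxa are found by a Wilcoxon signed-rank test on
relative abundances across (diseased, unaffected) pairs rarefied to the
pair minimum depth, with multiple-testing correction over the taxa
tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DiversityRecord",
    "PairedTestResult",
    "SampleTooShallow",
    "rarefy_counts",
    "expected_rarefied_richness",
    "alpha_diversity",
    "gini_simpson",
    "bray_curtis",
    "intra_inter_beta",
    "paired_site_test",
    "welch_t",
    "filter_antibiotic",
]

RAREFACTION_DEPTH = 50_000
EXACT_WILCOXON_MAX_N = 25
SMALL_N_PAIRS = 6


class SampleTooShallow(ValueError):
    """Raised when a sample has fewer reads than the rarefaction depth.

    The caller is expected to exclude the sample, mirroring the exclusion
    of samples below the common depth rather than silently truncating.
    """


@dataclass
class DiversityRecord:
    sample_id: str
    richness: int
    gini_simpson: float
    depth_used: int


@dataclass
class PairedTestResult:
    taxon: str
    n_pairs: int
    statistic: float
    p_raw: float
    p_adjusted: float
    direction: str  # "diseased_up" | "diseased_down" | "none"
    small_n_warning: bool = False


def rarefy_counts(
    counts: np.ndarray | pd.Series, depth: int, seed: int | np.random.Generator = 0
) -> np.ndarray | pd.Series:
    """Subsample a count vector to ``depth`` reads without replacement.

    Multivariate hypergeometric draw; the output sums to ``depth``
    exactly.  A sample with fewer than ``depth`` total reads raises
    :class:`SampleTooShallow`.
    """
    values = counts.to_numpy() if isinstance(counts, pd.Series) else np.asarray(counts)
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    total = int(values.sum())
    if depth > total:
        raise SampleTooShallow(f"sample has {total} reads, below depth {depth}")
    if depth == total:
        sub = values.astype(np.int64)
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        sub = rng.multivariate_hypergeometric(values.astype(np.int64), depth)
    if isinstance(counts, pd.Series):
        return pd.Series(sub, index=counts.index, name=counts.name)
    return sub


def expected_rarefied_richness(counts: np.ndarray, depth: int) -> float:
    """Closed-form expected richness after rarefying to ``depth``.

    E[S] = sum_i (1 - C(N - n_i, d) / C(N, d)) under the hypergeometric
    subsample; used as the analytic oracle for :func:`rarefy_counts`.
    """
    values = np.asarray(counts, dtype=np.int64)
    N = int(values.sum())
    if depth > N:
        raise SampleTooShallow(f"depth {depth} exceeds total {N}")
    # C(N-n, d)/C(N, d) via log-gammas for numerical safety
    def log_comb(n: int, k: int) -> float:
        if k < 0 or k > n:
            return -np.inf
        from scipy.special import gammaln

        return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))

    total = 0.0
    denom = log_comb(N, depth)
    for n_i in values:
        if n_i == 0:
            continue
        num = log_comb(N - int(n_i), depth)
        total += 1.0 - (np.exp(num - denom) if np.isfinite(num) else 0.0)
    return total


def gini_simpson(counts: np.ndarray | pd.Series) -> float:
    """1 - sum p_i^2 over relative abundances."""
    values = np.asarray(counts, dtype=float)
    total = values.sum()
    if total <= 0:
        raise ValueError("counts must have a positive total")
    p = values / total
    return float(1.0 - np.sum(p**2))


def alpha_diversity(counts: np.ndarray | pd.Series, sample_id: str = "sample") -> DiversityRecord:
    """Richness (taxa with count > 0) and Gini-Simpson evenness."""
    values = np.asarray(counts, dtype=np.int64)
    total = int(values.sum())
    if total <= 0:
        raise ValueError("counts must have a positive total")
    return DiversityRecord(
        sample_id=sample_id,
        richness=int((values > 0).sum()),
        gini_simpson=gini_simpson(values),
        depth_used=total,
    )


def bray_curtis(p: np.ndarray | pd.Series, q: np.ndarray | pd.Series) -> float:
    """Bray-Curtis distance 1 - sum min(p_i, q_i) on relative abundances.

    Both vectors must be indexed over the same (union) taxon set and sum
    to 1.
    """
    pv = np.asarray(p, dtype=float)
    qv = np.asarray(q, dtype=float)
    if pv.shape != qv.shape:
        raise ValueError("profiles must share one taxon axis")
    for name, v in (("p", pv), ("q", qv)):
        if not np.isclose(v.sum(), 1.0, atol=1e-6):
            raise ValueError(f"profile {name} must sum to 1 (got {v.sum():.6g})")
    # clamp: float cancellation can push 1 - sum(min) a few ulp outside [0, 1]
    return float(min(1.0, max(0.0, 1.0 - np.minimum(pv, qv).sum())))


def filter_antibiotic(counts: pd.DataFrame, metadata: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop samples whose patients received antibiotics."""
    flagged_patients = set(metadata.loc[metadata["antibiotic_flag"], "patient"])
    keep = ~metadata["patient"].isin(flagged_patients)
    kept_ids = metadata.index[keep]
    return counts.loc[kept_ids], metadata.loc[kept_ids]


def intra_inter_beta(
    counts: pd.DataFrame, metadata: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Intra-subject vs inter-subject Bray-Curtis distance distributions.

    All unordered sample pairs are computed once and split by whether the
    two samples come from the same patient.  The accompanying rank-sum
    comparison is descriptive only: pairwise distances share samples and
    are not independent, so its p-value must not be read as a calibrated
    test.
    """
    patients = metadata["patient"]
    n_per_patient = patients.value_counts()
    if (n_per_patient >= 2).sum() < 1 or len(n_per_patient) < 2:
        raise ValueError("need >= 2 patients and >= 1 patient with >= 2 samples")
    rel = counts.div(counts.sum(axis=1), axis=0)
    ids = list(counts.index)
    intra, inter = [], []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            d = bray_curtis(rel.loc[ids[i]], rel.loc[ids[j]])
            if patients[ids[i]] == patients[ids[j]]:
                intra.append(d)
            else:
                inter.append(d)
    intra_arr, inter_arr = np.array(intra), np.array(inter)
    if intra_arr.size and inter_arr.size and (intra_arr.var() + inter_arr.var()) > 0:
        stat, p = stats.mannwhitneyu(intra_arr, inter_arr, alternative="two-sided")
    else:
        stat, p = np.nan, np.nan
    summary = {
        "intra_mean": float(intra_arr.mean()) if intra_arr.size else np.nan,
        "inter_mean": float(inter_arr.mean()) if inter_arr.size else np.nan,
        "rank_sum_statistic": float(stat),
        "rank_sum_p": float(p),
        "note": "descriptive only: pairwise distances are not independent",
    }
    return intra_arr, inter_arr, summary


def _wilcoxon_signed_rank(diffs: np.ndarray) -> tuple[float, float]:
    """Signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon convention), ties are
    mid-ranked; the exact null distribution is used for n <= 25 without
    ties, otherwise the normal approximation with continuity correction.
    """
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return 0.0, 1.0
    has_ties = len(np.unique(np.abs(nz))) < nz.size
    if nz.size <= EXACT_WILCOXON_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(
        nz, zero_method="wilcox", correction=(method == "approx"), method=method
    )
    return float(res.statistic), float(res.pvalue)


def paired_site_test(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    taxa: list[str] | None = None,
    site: str | None = None,
    correction: str = "fdr_bh",
    seed: int = 0,
) -> list[PairedTestResult]:
    """Wilcoxon signed-rank test of diseased vs unaffected paired sites.

    Eligible patients contribute exactly one diseased and one unaffected
    sample of the same site class (contralateral sides).  Each pair is
    rarefied to its minimum depth (seeded) before converting to relative
    abundances.  ``correction`` is any method accepted by statsmodels'
    ``multipletests`` ("fdr_bh", "bonferroni", "holm", ...).
    """
    counts, metadata = filter_antibiotic(counts, metadata)
    meta = metadata if site is None else metadata[metadata["site"] == site]
    pairs = []
    for (patient, site_name), grp in meta.groupby(["patient", "site"], sort=True):
        diseased = grp.index[grp["disease_state"] == "diseased"]
        unaffected = grp.index[grp["disease_state"] == "unaffected"]
        if len(diseased) == 1 and len(unaffected) == 1:
            pairs.append((diseased[0], unaffected[0]))
    if not pairs:
        raise ValueError("no eligible (diseased, unaffected) pairs")
    if taxa is None:
        taxa = list(counts.columns)
    missing = set(taxa) - set(counts.columns)
    if missing:
        raise ValueError(f"taxa absent from the count table: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    dis_rel, una_rel = [], []
    for d_id, u_id in pairs:
        depth = int(min(counts.loc[d_id].sum(), counts.loc[u_id].sum()))
        d_sub = rarefy_counts(counts.loc[d_id], depth, rng)
        u_sub = rarefy_counts(counts.loc[u_id], depth, rng)
        dis_rel.append(d_sub / depth)
        una_rel.append(u_sub / depth)
    dis_df = pd.DataFrame(dis_rel)
    una_df = pd.DataFrame(una_rel)
    small_n = len(pairs) < SMALL_N_PAIRS
    stats_raw = []
    for taxon in taxa:
        diffs = (dis_df[taxon].to_numpy() - una_df[taxon].to_numpy()).astype(float)
        stat, p = _wilcoxon_signed_rank(diffs)
        med = float(np.median(diffs))
        direction = "diseased_up" if med > 0 else ("diseased_down" if med < 0 else "none")
        stats_raw.append((taxon, stat, p, direction))
    p_adj = multipletests([s[2] for s in stats_raw], method=correction)[1]
    return [
        PairedTestResult(
            taxon=t,
            n_pairs=len(pairs),
            statistic=stat,
            p_raw=p,
            p_adjusted=float(pa),
            direction=direction,
            small_n_warning=small_n,
        )
        for (t, stat, p, direction), pa in zip(stats_raw, p_adj)
    ]


def welch_t(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Welch's unequal-variance t-test (two-sided).

    Requires n >= 2 per group and positive variance in at least one
    group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("both groups have zero variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def write_diversity(records: list[DiversityRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "richness": r.richness,
                "gini_simpson": f"{r.gini_simpson:.6f}",
                "depth_used": r.depth_used,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def write_paired_results(results: list[PairedTestResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "taxon": r.taxon,
                "n_pairs": r.n_pairs,
                "statistic": f"{r.statistic:.4g}",
                "p_raw": f"{r.p_raw:.6g}",
                "p_adjusted": f"{r.p_adjusted:.6g}",
                "direction": r.direction,
                "small_n_warning": r.small_n_warning,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)
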