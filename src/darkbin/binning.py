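"""K-means binning of taxonomically dark contigs and automated curation.

Contigs that escaped species assignment are clustered on (GC content,
log10 coverage), both standardised; the number of clusters is chosen by
mean silhouette over K = 2..k_max with a floor below which everything
stays in one bin.  Curation then keeps only bins that are internally
consistent (every member within 5% relative GC deviation and 25%
relative coverage deviation from the bin median) and discretely
separated from the other bins (centroid distance over within-bin RMS
radius above a dimensionless threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .seqio import Contig, gc_fraction
from .taxonomy import TaxonBin

__all__ = [
    "BinCuration",
    "gc_content",
    "contig_features",
    "cluster_unassigned",
    "curate_bins",
    "write_curation",
    "write_scatter",
]

GC_TOL = 0.05
COV_TOL = 0.25
SEP_THRESHOLD = 2.0
SILHOUETTE_FLOOR = 0.45
MIN_BIN_CONTIGS = 5
MIN_BIN_LENGTH = 50_000


def gc_content(seq: str) -> float:
    """GC fraction over unambiguous bases (error on empty/ambiguous-only)."""
    return gc_fraction(seq)


@dataclass
class BinCuration:
    bin_id: str
    n_contigs: int
    total_length: int
    gc_mean: float
    gc_max_rel_dev: float
    cov_median: float
    cov_max_rel_dev: float
    separation_score: float
    status: str  # curated | rejected
    reject_reason: str = ""


def contig_features(contigs: list[Contig]) -> np.ndarray:
    """Standardised (GC, log10 coverage) feature matrix."""
    raw = np.array([[gc_content(c.seq), np.log10(c.coverage)] for c in contigs])
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0)
    sd[sd == 0] = 1.0
    return (raw - mean) / sd


def cluster_unassigned(
    contigs: list[Contig],
    k_max: int = 8,
    seed: int = 0,
    silhouette_floor: float = SILHOUETTE_FLOOR,
) -> tuple[dict[str, TaxonBin], np.ndarray, np.ndarray]:
    """Preliminary K-means binning on standardised (GC, log10 coverage).

    K is chosen in 2..k_max by maximum mean silhouette; when even the
    best silhouette is below the floor the residual set is left as a
    single bin.  Returns (bins, labels, features); fewer than two contigs
    yield one trivial bin.
    """
    if len(contigs) < 2:
        feats = contig_features(contigs) if contigs else np.zeros((0, 2))
        bins = (
            {"bin00": TaxonBin("bin00", list(contigs), status="preliminary")}
            if contigs
            else {}
        )
        return bins, np.zeros(len(contigs), dtype=int), feats
    feats = contig_features(contigs)
    candidates: list[tuple[int, float, np.ndarray]] = []
    upper = min(k_max, len(contigs) - 1)
    for k in range(2, upper + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(feats)
        if len(set(labels)) < 2:
            continue
        candidates.append((k, silhouette_score(feats, labels), labels))
    best_labels = None
    if candidates:
        best_sil = max(sil for _, sil, _ in candidates)
        if best_sil >= silhouette_floor:
            # parsimony tie-break: smallest K within 0.05 of the best
            # silhouette, so a flat silhouette curve cannot over-split
            for k, sil, labels in candidates:
                if sil >= best_sil - 0.05:
                    best_labels = labels
                    break
    if best_labels is None:
        best_labels = np.zeros(len(contigs), dtype=int)
    # renumber clusters by first appearance for a stable, readable order
    order: dict[int, int] = {}
    for lab in best_labels:
        if lab not in order:
            order[lab] = len(order)
    labels = np.array([order[lab] for lab in best_labels])
    bins: dict[str, TaxonBin] = {}
    for idx, lab in enumerate(labels):
        bid = f"bin{lab:02d}"
        bins.setdefault(bid, TaxonBin(bid, [], status="preliminary")).contigs.append(
            contigs[idx]
        )
    return bins, labels, feats


def _max_rel_dev(values: np.ndarray) -> tuple[float, float]:
    """(median, max |v - median| / median) for positive-valued features."""
    med = float(np.median(values))
    if med == 0:
        return 0.0, np.inf
    return med, float(np.max(np.abs(values - med) / med))


def curate_bins(
    bins: dict[str, TaxonBin],
    features: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    gc_tol: float = GC_TOL,
    cov_tol: float = COV_TOL,
    sep_threshold: float = SEP_THRESHOLD,
    min_contigs: int = MIN_BIN_CONTIGS,
    min_total_length: int = MIN_BIN_LENGTH,
) -> tuple[dict[str, TaxonBin], dict[str, TaxonBin], list[BinCuration]]:
    """Apply the consistency and separation criteria to preliminary bins.

    A bin is curated iff every member sits within ``gc_tol`` relative GC
    deviation and ``cov_tol`` relative coverage deviation of the bin
    medians, its centroid is separated from the nearest other centroid by
    more than ``sep_threshold`` within-bin RMS radii (in the standardised
    feature space used for clustering), and it is large enough to support
    downstream ANI/phylogeny.  Everything else is rejected with a reason.
    """
    bin_ids = sorted(bins)
    if features is None or labels is None:
        all_contigs = [c for b in bin_ids for c in bins[b].contigs]
        features = contig_features(all_contigs)
        labels_list = []
        for i, b in enumerate(bin_ids):
            labels_list += [i] * bins[b].n_contigs
        labels = np.array(labels_list)
    centroids = {}
    radii = {}
    for i, b in enumerate(bin_ids):
        pts = features[labels == i]
        centroids[b] = pts.mean(axis=0)
        radii[b] = float(np.sqrt(np.mean(np.sum((pts - pts.mean(axis=0)) ** 2, axis=1))))
    curated: dict[str, TaxonBin] = {}
    rejected: dict[str, TaxonBin] = {}
    records: list[BinCuration] = []
    for b in bin_ids:
        tb = bins[b]
        gcs = np.array([gc_content(c.seq) for c in tb.contigs])
        covs = np.array([c.coverage for c in tb.contigs])
        gc_med, gc_dev = _max_rel_dev(gcs)
        cov_med, cov_dev = _max_rel_dev(covs)
        if len(bin_ids) > 1:
            nearest = min(
                float(np.linalg.norm(centroids[b] - centroids[o]))
                for o in bin_ids
                if o != b
            )
            sep = nearest / radii[b] if radii[b] > 0 else np.inf
        else:
            sep = np.inf
        reasons = []
        if tb.n_contigs < min_contigs or tb.total_length < min_total_length:
            reasons.append("size")
        if gc_dev >= gc_tol:
            reasons.append("gc_consistency")
        if cov_dev >= cov_tol:
            reasons.append("cov_consistency")
        if not sep > sep_threshold:
            reasons.append("separation")
        status = "curated" if not reasons else "rejected"
        tb.status = status
        (curated if not reasons else rejected)[b] = tb
        records.append(
            BinCuration(
                bin_id=b,
                n_contigs=tb.n_contigs,
                total_length=tb.total_length,
                gc_mean=float(gcs.mean()),
                gc_max_rel_dev=gc_dev,
                cov_median=cov_med,
                cov_max_rel_dev=cov_dev,
                separation_score=float(sep),
                status=status,
                reject_reason=",".join(reasons),
            )
        )
    return curated, rejected, records


def write_curation(records: list[BinCuration], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "bin_id": r.bin_id,
                "n_contigs": r.n_contigs,
                "total_length": r.total_length,
                "gc_mean": f"{r.gc_mean:.4f}",
                "gc_max_rel_dev": f"{r.gc_max_rel_dev:.4f}",
                "cov_median": f"{r.cov_median:.4g}",
                "cov_max_rel_dev": f"{r.cov_max_rel_dev:.4f}",
                "separation_score": f"{r.separation_score:.4g}",
                "status": r.status,
                "reject_reason": r.reject_reason or "NA",
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def write_scatter(
    contigs: list[Contig], labels: np.ndarray, statuses: dict[str, str], path: str | Path
) -> None:
    """GC vs log10-coverage scatter table for bin-plot reproduction."""
    rows = []
    for c, lab in zip(contigs, labels):
        bid = f"bin{lab:02d}"
        rows.append(
            {
                "contig_id": c.id,
                "gc": f"{gc_content(c.seq):.4f}",
                "log10_cov": f"{np.log10(c.coverage):.4f}",
                "bin": bid,
                "status": statuses.get(bid, "preliminary"),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
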