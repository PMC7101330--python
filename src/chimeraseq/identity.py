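"""Cluster-level identity analysis: lightweight clustering, mean
expression profiles, cluster cross-correlation, dot-plot marker
statistics, and per-gene Z-scores.

Clustering here is plumbing (PCA followed by k-means on log-normalized
values); externally supplied labels are first-class and returned
verbatim.  The scientific outputs are the cluster mean profiles and
their Pearson cross-correlation over a shared gene namespace — the
statistic that identifies a xenografted human microglia cluster by its
high correlation with the host's mouse microglia cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantify import LOG_NORMALIZED, CountMatrix

PROVIDED = "provided"
INTERNAL = "internal"


@dataclass
class ClusterLabels:
    labels: pd.Series  # barcode -> cluster id
    provenance: str  # provided | internal

    def validate_against(self, matrix: CountMatrix) -> None:
        idx = pd.Index(matrix.barcodes)
        if not idx.isin(self.labels.index).all() or self.labels.index.has_duplicates:
            raise ValueError("labels must cover every matrix barcode exactly once")


def cluster_cells(
    matrix: CountMatrix,
    k: int = 2,
    seed: int = 0,
    n_components: int = 20,
    provided: pd.Series | None = None,
) -> ClusterLabels:
    """K-means labels on a PCA reduction of log-normalized values.

    Deterministic given ``seed``.  When ``provided`` labels are given
    they are validated and passed through unchanged.
    """
    if provided is not None:
        out = ClusterLabels(labels=provided.rename("cluster"), provenance=PROVIDED)
        out.validate_against(matrix)
        return out
    if matrix.normalization != LOG_NORMALIZED:
        raise ValueError("clustering expects a log-normalized matrix")
    n = len(matrix.barcodes)
    if n < 2:
        raise ValueError("need at least 2 barcodes to cluster")
    if k > n:
        raise ValueError(f"k={k} exceeds {n} barcodes")
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    X = matrix.counts.toarray()
    d = min(n_components, n - 1, X.shape[1])
    if d >= 2:
        X = PCA(n_components=d, random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(X)
    labels = pd.Series(km.labels_, index=pd.Index(matrix.barcodes), name="cluster")
    return ClusterLabels(labels=labels, provenance=INTERNAL)


def cluster_mean_profiles(
    matrix: CountMatrix, labels: ClusterLabels
) -> tuple[pd.DataFrame, pd.Series]:
    """Arithmetic mean log-normalized expression per cluster.

    Returns (profiles: clusters x genes, n_cells per cluster).
    """
    labels.validate_against(matrix)
    lab = labels.labels.reindex(pd.Index(matrix.barcodes))
    groups = pd.Index(lab.unique())
    if (lab.value_counts() < 1).any():
        raise ValueError("empty cluster")
    rows = []
    sizes = {}
    for c in sorted(groups, key=str):
        mask = (lab == c).to_numpy()
        rows.append(np.asarray(matrix.counts[mask].mean(axis=0)).ravel())
        sizes[c] = int(mask.sum())
    profiles = pd.DataFrame(rows, index=sorted(groups, key=str), columns=matrix.genes)
    return profiles, pd.Series(sizes, name="n_cells")


def cross_correlate_clusters(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between cluster mean profiles.

    Profiles are clusters x genes on a common namespace; genes missing
    (NaN) in either profile of a pair are excluded pairwise.  A
    zero-variance profile yields NaN against every partner (undefined,
    not zero).  The result is symmetric with a unit diagonal wherever
    defined.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    corr = profiles.T.corr(method="pearson", min_periods=2)
    for c in corr.index:
        if np.isfinite(corr.at[c, c]):
            corr.at[c, c] = 1.0
    return corr


def marker_dot_stats(
    matrix: CountMatrix,
    labels: ClusterLabels,
    genes: list[str],
) -> tuple[pd.DataFrame, list[str]]:
    """Dot-plot statistics per (cluster, gene).

    ``percent_expression`` is the percentage of the cluster's cells
    with a nonzero count for the gene (nonzero is preserved by log
    normalization, so either state of the matrix gives the same
    percentage); ``average_expression`` is the mean log-normalized
    value.  Panel genes absent from the matrix are returned separately
    and skipped.
    """
    if not genes:
        raise ValueError("empty gene panel")
    labels.validate_against(matrix)
    present = [g for g in genes if g in set(matrix.genes)]
    absent = [g for g in genes if g not in set(matrix.genes)]
    gpos = pd.Series(range(len(matrix.genes)), index=matrix.genes)
    lab = labels.labels.reindex(pd.Index(matrix.barcodes))
    rows = []
    for c in sorted(pd.Index(lab.unique()), key=str):
        mask = (lab == c).to_numpy()
        sub = matrix.counts[mask][:, gpos[present].to_numpy()]
        n = int(mask.sum())
        pct = np.asarray((sub > 0).sum(axis=0)).ravel() / n * 100.0
        avg = np.asarray(sub.mean(axis=0)).ravel()
        for g, p, a in zip(present, pct, avg):
            rows.append((c, g, p, a))
    stats = pd.DataFrame(
        rows, columns=["cluster", "gene", "percent_expression", "average_expression"]
    )
    return stats, absent


def gene_zscore(values: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Z-scores across samples (genes x samples).

    (x - mean) / sd with the n-1 denominator, so each non-degenerate
    row has mean 0 and sample sd 1.  Zero-spread rows become all zeros
    with a warning; fewer than 2 samples is an error.
    """
    if values.shape[1] < 2:
        raise ValueError("Z-scores need at least 2 samples")
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero spread: Z-scores set to 0"
        )
    safe_sd = sd.replace(0, np.nan)
    z = values.sub(mean, axis=0).div(safe_sd, axis=0)
    return z.fillna(0.0) if degenerate.any() else z
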