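"""Time-series analysis of ct-siRNA accumulation across growth stages.

Genes are filtered by an abundance floor (TPM above a threshold in at least
two stages) and by dynamic range (absolute log2 fold change above a
threshold when comparing any two stages, computed with a +1 pseudocount on
TPM so comparisons at zero stay defined). Filtered trajectories are z-scored
per gene and clustered hierarchically (Euclidean distance, complete linkage,
tree cut to k flat clusters); each cluster's mean trajectory is labelled
increasing, decreasing or other by Spearman correlation with stage order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


def stage_filter(
    matrix: pd.DataFrame,
    min_tpm: float = 10.0,
    min_stages: int = 2,
    min_abs_lfc: float = 1.0,
) -> list[str]:
    """Select dynamically accumulating genes from a genes x stages TPM table.

    A gene is kept iff it has TPM strictly above ``min_tpm`` in at least
    ``min_stages`` stages AND the maximum over stage pairs of
    ``|log2((TPM_i + 1) / (TPM_j + 1))|`` strictly exceeds ``min_abs_lfc``.
    Raising either threshold can only shrink the kept set.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 stages")
    X = matrix.to_numpy(dtype=float)
    abundant = (X > min_tpm).sum(axis=1) >= min_stages
    logs = np.log2(X + 1.0)
    dynamic_range = logs.max(axis=1) - logs.min(axis=1)
    keep = abundant & (dynamic_range > min_abs_lfc)
    return [g for g, k in zip(matrix.index, keep) if k]


def zscore_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Row z-scores (mean 0, sd 1); zero-variance rows become all-zero, flagged."""
    X = matrix.to_numpy(dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    flat = (sd[:, 0] == 0.0)
    sd_safe = np.where(sd == 0.0, 1.0, sd)
    Z = (X - mean) / sd_safe
    Z[flat] = 0.0
    zmat = pd.DataFrame(Z, index=matrix.index, columns=matrix.columns)
    return zmat, [g for g, f in zip(matrix.index, flat) if f]


@dataclass
class ClusterAssignment:
    """Flat clustering of gene trajectories plus per-cluster summaries."""

    labels: pd.Series  # gene -> cluster id (1..k)
    means: pd.DataFrame  # clusters x stages, z-scored mean trajectories
    trends: pd.Series  # cluster id -> {increasing, decreasing, other}
    flat_genes: list[str]


def trend_class(trajectory: np.ndarray, threshold: float = 0.8) -> str:
    """Label a trajectory by Spearman correlation with stage index.

    ``increasing`` iff rho >= +threshold, ``decreasing`` iff rho <= -threshold,
    else ``other``. Constant trajectories are ``other``.
    """
    y = np.asarray(trajectory, dtype=float)
    if y.size < 2:
        raise ValueError("trajectory needs >= 2 stages")
    if np.all(y == y[0]):
        return "other"
    rho = stats.spearmanr(np.arange(y.size), y).statistic
    if rho >= threshold:
        return "increasing"
    if rho <= -threshold:
        return "decreasing"
    return "other"


def cluster_trends(matrix: pd.DataFrame, k: int = 18) -> ClusterAssignment:
    """Cluster z-scored gene trajectories into k flat clusters.

    Deterministic: Euclidean distance on row z-scores, complete linkage,
    ``cut_tree`` to k clusters; cluster ids are renumbered 1..k by order of
    first appearance along the input gene order. Requires at least k genes.
    """
    if len(matrix) < k:
        raise ValueError(f"need >= k={k} genes, got {len(matrix)}")
    zmat, flat_genes = zscore_rows(matrix)
    Z = hierarchy.linkage(pdist(zmat.to_numpy(), metric="euclidean"), method="complete")
    raw = hierarchy.cut_tree(Z, n_clusters=k).ravel()
    remap: dict[int, int] = {}
    labels = np.empty(raw.size, dtype=int)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap) + 1
        labels[i] = remap[r]
    label_series = pd.Series(labels, index=matrix.index, name="cluster")
    means = zmat.groupby(label_series).mean()
    trends = pd.Series(
        {cid: trend_class(means.loc[cid].to_numpy()) for cid in means.index},
        name="trend",
    )
    return ClusterAssignment(label_series, means, trends, flat_genes)
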