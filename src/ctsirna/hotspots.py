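"""Hotspot source-gene ranking and cross-genotype union.

A hotspot gene is a source gene among the top N (default 20) ranked by
accumulated antisense 22-nt ct-siRNA abundance within a genotype. Ranking
uses replicate-mean TPM; sense-strand reads are excluded by construction
because the count matrices carry only the antisense slice.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


def rank_sources(tpm: pd.DataFrame, genotype_samples: Sequence[str]) -> pd.DataFrame:
    """Rank genes by replicate-mean TPM for one genotype.

    ``tpm`` is genes x samples. Returns a DataFrame with columns
    ``rank gene tpm share cum_share`` sorted descending by abundance, ties
    broken by gene identifier (stable). Genes with zero abundance are
    omitted; a zero total yields an empty report.
    """
    mean = tpm[list(genotype_samples)].mean(axis=1)
    total = float(mean.sum())
    if total <= 0:
        return pd.DataFrame(columns=["rank", "gene", "tpm", "share", "cum_share"])
    mean = mean[mean > 0]
    order = sorted(mean.index, key=lambda g: (-mean[g], g))
    shares = np.array([mean[g] / total for g in order])
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "gene": order,
            "tpm": [mean[g] for g in order],
            "share": shares,
            "cum_share": np.cumsum(shares),
        }
    )


def top_n_share(report: pd.DataFrame, n: int = 20) -> float:
    """Cumulative abundance share of the top-n ranked source genes."""
    if n <= 0 or report.empty:
        return 0.0
    return float(report["share"].iloc[: min(n, len(report))].sum())


def hotspot_union(
    reports: Mapping[str, pd.DataFrame], n: int = 20
) -> tuple[list[str], pd.DataFrame]:
    """Union of per-genotype top-n gene sets, with a membership matrix.

    Returns (sorted union gene list, genotypes x genes boolean DataFrame
    whose row sums reproduce the per-genotype top-n sizes).
    """
    if not reports:
        raise ValueError("at least one genotype report required")
    tops = {
        genotype: list(rep["gene"].iloc[: min(n, len(rep))])
        for genotype, rep in reports.items()
    }
    union = sorted(set().union(*[set(t) for t in tops.values()]))
    membership = pd.DataFrame(
        {g: [g in set(tops[geno]) for geno in reports] for g in union},
        index=list(reports),
    )
    return union, membership


def cluster_samples(
    relative_matrix: pd.DataFrame,
) -> tuple[np.ndarray, list[str]]:
    """Hierarchical clustering of samples on relative ct-siRNA profiles.

    ``relative_matrix`` is genes x samples (e.g. per-sample log2 ratios to a
    control). Euclidean distance, complete linkage, computed over sample
    columns. Returns (scipy linkage matrix, leaf order as sample names);
    scipy's deterministic tie handling plus the fixed input column order make
    the dendrogram reproducible. A constant matrix degenerates to a single
    cluster (all merge heights zero) with a warning.
    """
    samples = list(relative_matrix.columns)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to cluster")
    X = relative_matrix.to_numpy(dtype=float).T
    dist = pdist(X, metric="euclidean")
    if np.allclose(dist, 0.0):
        import warnings

        warnings.warn("constant relative-expression matrix: all samples identical")
    Z = hierarchy.linkage(dist, method="complete")
    leaves = hierarchy.leaves_list(Z)
    return Z, [samples[i] for i in leaves]


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def recurse(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({recurse(tree.left, tree.dist)},{recurse(tree.right, tree.dist)});"
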