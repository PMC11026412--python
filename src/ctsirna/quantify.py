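"""Normalization and differential ct-siRNA accumulation.

Counts are antisense tag counts per gene for one size class (typically 21 or
22 nt). Two normalizations are provided: tags-per-million against the full
mapped library (for reporting and ranking) and median-of-ratios size factors
(for the count model, so that a handful of explosive hotspot genes cannot
drag every other gene's fold change).

The differential test is a self-contained negative-binomial Wald test:

1. per-gene method-of-moments dispersion on size-factor-normalized counts,
   pooled within condition groups;
2. a mean-dispersion trend ``alpha(mu) = a0 + a1 / mu`` fitted across genes;
   with the few replicates typical of sRNA-seq designs the genewise moments
   estimates carry almost no information, so the working dispersion is the
   trend value, escalated to the genewise estimate for outlier genes whose
   moments estimate exceeds twice the trend (the same guard DESeq-style
   testing applies to dispersion outliers);
3. per-group NB log-link fits with size-factor offsets (Newton iterations,
   vectorized across genes) and a Wald statistic on the log2 fold change
   referred to the standard normal;
4. Benjamini-Hochberg correction across genes passing an independent
   low-count filter (baseMean below the floor reports padj = NA).

Fold changes where one side is all zero are reported with a +1 pseudocount
on the normalized means so heatmaps stay finite.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

_LN2 = np.log(2.0)
_MIN_ALPHA = 1e-8
_MAX_ALPHA = 10.0


def tpm_normalize(counts: pd.DataFrame, library_totals: pd.Series) -> pd.DataFrame:
    """Tags per million mapped tags: count / library_total * 1e6.

    ``library_totals`` are per-sample totals of all mapped in-range tags (not
    just the counted subset), so column sums of the result equal
    1e6 * assigned/total.
    """
    totals = library_totals.reindex(counts.columns)
    if totals.isna().any():
        missing = list(totals.index[totals.isna()])
        raise ValueError(f"library totals missing for samples: {missing}")
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero library total for samples: {bad}")
    return counts.div(totals, axis=1) * 1e6


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors.

    The pseudo-reference is the genewise geometric mean; each sample's factor
    is the median ratio to it over genes with no zero anywhere. If no such
    gene exists, falls back to library-size factors (column sums scaled to
    geometric mean 1) with a warning.
    """
    mat = counts.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        import warnings

        warnings.warn("no gene free of zeros; falling back to library-size factors")
        totals = mat.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("cannot compute size factors: empty sample column")
        factors = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(factors, index=counts.columns, name="size_factor")
    sub = mat[nonzero]
    geo = np.exp(np.mean(np.log(sub), axis=1, keepdims=True))
    factors = np.median(sub / geo, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values; NaNs propagate and are not counted."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    if m == 0:
        return out
    ps = p[ok]
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def _fit_group(
    y: np.ndarray, s: np.ndarray, alpha: np.ndarray, n_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized NB log-link MLE of one mean parameter per gene.

    ``y``: genes x samples counts for one group; ``s``: size factors;
    ``alpha``: per-gene dispersion. Returns (beta, fisher_info) where
    mu_ij = s_j * exp(beta_i).
    """
    pseudo = (y.sum(axis=1) == 0)
    yy = y + np.where(pseudo, 0.5, 0.0)[:, None]
    beta = np.log(yy.sum(axis=1) / s.sum())
    for _ in range(n_iter):
        mu = s[None, :] * np.exp(beta)[:, None]
        denom = 1.0 + alpha[:, None] * mu
        score = ((yy - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        beta = beta + np.clip(step, -5, 5)
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = s[None, :] * np.exp(beta)[:, None]
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    return beta, info


def _moments_dispersion(
    y: np.ndarray, s: np.ndarray, groups: list[np.ndarray]
) -> np.ndarray:
    """Pooled within-group method-of-moments dispersion per gene."""
    q = y / s[None, :]
    num = np.zeros(y.shape[0])
    den = np.zeros(y.shape[0])
    for idx in groups:
        if idx.size < 2:
            continue
        m = q[:, idx].mean(axis=1)
        v = q[:, idx].var(axis=1, ddof=1)
        c = np.mean(1.0 / s[idx])
        df = idx.size - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m * c) / m**2
        a = np.where(np.isfinite(a), a, 0.0)
        num += df * a
        den += df
    alpha = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    return np.clip(alpha, _MIN_ALPHA, _MAX_ALPHA)


def _dispersion_trend(alpha_hat: np.ndarray, base_mean: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu over informative genes; predict for all."""
    use = (alpha_hat > 10 * _MIN_ALPHA) & (base_mean > 0)
    if use.sum() < 10:
        fill = float(np.median(alpha_hat[alpha_hat > 0])) if (alpha_hat > 0).any() else 0.01
        return np.full_like(alpha_hat, max(fill, _MIN_ALPHA))
    X = np.column_stack([np.ones(use.sum()), 1.0 / base_mean[use]])
    coef, *_ = np.linalg.lstsq(X, alpha_hat[use], rcond=None)
    a0, a1 = max(coef[0], _MIN_ALPHA), max(coef[1], 0.0)
    with np.errstate(divide="ignore"):
        pred = a0 + a1 / np.maximum(base_mean, 1e-8)
    return np.clip(pred, _MIN_ALPHA, _MAX_ALPHA)


def nb_test(
    counts: pd.DataFrame,
    mutant_samples: Sequence[str],
    control_samples: Sequence[str],
    base_mean_floor: float = 1.0,
    shrink_weight: float = 1.0,
) -> pd.DataFrame:
    """Negative-binomial Wald test of mutant vs control per gene.

    Returns a DataFrame with columns ``gene baseMean log2FC pvalue padj``.
    Genes below ``base_mean_floor`` (mean of size-factor-normalized counts)
    are reported but excluded from testing (pvalue/padj NA). The test is
    antisymmetric: swapping the contrast sides negates log2FC and leaves
    p-values unchanged.
    """
    mutant_samples = list(mutant_samples)
    control_samples = list(control_samples)
    if not mutant_samples or not control_samples:
        raise ValueError("both contrast sides must contain at least one sample")
    samples = mutant_samples + control_samples
    y = counts[samples].to_numpy(dtype=float)
    sf = size_factors(counts[samples]).to_numpy()
    idx_mut = np.arange(len(mutant_samples))
    idx_ctl = np.arange(len(mutant_samples), len(samples))

    q = y / sf[None, :]
    base_mean = q.mean(axis=1)

    if len(mutant_samples) >= 2 and len(control_samples) >= 2:
        alpha_hat = _moments_dispersion(y, sf, [idx_mut, idx_ctl])
    else:
        # 1 vs 1: no within-group replication; borrow entirely from the trend
        alpha_hat = _moments_dispersion(y, sf, [np.arange(len(samples))])
        shrink_weight = 1.0
    alpha_trend = _dispersion_trend(alpha_hat, base_mean)
    log_a = (1.0 - shrink_weight) * np.log(np.maximum(alpha_hat, _MIN_ALPHA)) + (
        shrink_weight
    ) * np.log(alpha_trend)
    alpha = np.clip(np.exp(log_a), _MIN_ALPHA, _MAX_ALPHA)
    # dispersion-outlier guard: never trust the trend below a genewise
    # estimate that clearly exceeds it
    alpha = np.where(alpha_hat > 2.0 * alpha_trend, alpha_hat, alpha)

    beta_m, info_m = _fit_group(y[:, idx_mut], sf[idx_mut], alpha)
    beta_c, info_c = _fit_group(y[:, idx_ctl], sf[idx_ctl], alpha)

    lfc = (beta_m - beta_c) / _LN2
    se = np.sqrt(1.0 / np.maximum(info_m, 1e-12) + 1.0 / np.maximum(info_c, 1e-12)) / _LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = lfc / se
    pvalue = 2.0 * stats.norm.sf(np.abs(wald))

    # reporting conventions at the zero boundary
    mean_m = q[:, idx_mut].mean(axis=1)
    mean_c = q[:, idx_ctl].mean(axis=1)
    zero_side = (mean_m == 0) | (mean_c == 0)
    lfc = np.where(zero_side, np.log2((mean_m + 1.0) / (mean_c + 1.0)), lfc)
    all_zero = (mean_m == 0) & (mean_c == 0)
    lfc = np.where(all_zero, 0.0, lfc)
    pvalue = np.where(all_zero, np.nan, pvalue)

    tested = base_mean >= base_mean_floor
    pvalue = np.where(tested, pvalue, np.nan)
    padj = benjamini_hochberg(pvalue)

    return pd.DataFrame(
        {
            "gene": counts.index,
            "baseMean": base_mean,
            "log2FC": lfc,
            "pvalue": pvalue,
            "padj": padj,
        }
    ).set_index("gene")


def call_differential(
    result: pd.DataFrame, padj_max: float = 0.05, min_abs_lfc: float = 1.0
) -> list[str]:
    """Genes with padj < padj_max and |log2FC| > min_abs_lfc (NA excluded)."""
    if result.empty:
        return []
    keep = (result["padj"] < padj_max) & (result["log2FC"].abs() > min_abs_lfc)
    keep &= result["padj"].notna()
    return sorted(result.index[keep])


def fc_strata(
    result: pd.DataFrame, bin_edges: Sequence[float]
) -> dict[tuple[float, float], list[str]]:
    """Group genes into half-open log2FC bins [e_i, e_{i+1}).

    Genes outside every bin are omitted. Edges must be strictly increasing.
    """
    edges = list(bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])) or len(edges) < 2:
        raise ValueError("bin_edges must be strictly increasing with >= 2 edges")
    out: dict[tuple[float, float], list[str]] = {
        (lo, hi): [] for lo, hi in zip(edges, edges[1:])
    }
    for gene, lfc in result["log2FC"].items():
        for lo, hi in out:
            if lo <= lfc < hi:
                out[(lo, hi)].append(gene)
                break
    for key in out:
        out[key].sort()
    return out
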