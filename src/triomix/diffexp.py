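"""Two-group negative-binomial differential expression for count matrices.

The stage mirrors the standard RNA-seq workflow: low-count prefiltering,
median-of-ratios size-factor normalisation, per-feature method-of-moments
dispersion, a Wald test on the log2 fold change (delta method standard
error) and Benjamini-Hochberg adjustment.  No empirical-Bayes dispersion
sharing and no fold-change shrinkage are applied: downstream integration
consumes only signed fold changes and significance calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from triomix.io_formats import CountMatrix, SampleMetadata

LN2 = np.log(2.0)
#: floor for the method-of-moments NB dispersion estimate
MIN_DISPERSION = 1e-8
#: pseudo-count used in the fold-change ratio (never in the NB moments)
PSEUDO = 0.5

RESULT_COLUMNS = ["feature_id", "base_mean", "log2fc", "se", "p", "padj", "significant"]


def prefilter(cm: CountMatrix, min_total: int = 10) -> CountMatrix:
    """Drop features whose total count across all samples is below ``min_total``.

    A feature is retained iff its row sum is >= ``min_total``; order is
    preserved.
    """
    totals = cm.counts.sum(axis=1)
    keep = totals[totals >= min_total].index
    if len(keep) == 0:
        raise ValueError(
            f"prefilter(min_total={min_total}) removed every feature; "
            "review the threshold or the input matrix"
        )
    return cm.subset_features(keep)


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j, ``s_j`` is the median over reference features i
    (features positive in every sample) of ``count_ij / geomean_i``.
    """
    counts = cm.counts.to_numpy(dtype=float)
    all_positive = np.all(counts > 0, axis=1)
    if not all_positive.any():
        raise ValueError(
            "no feature is positive in every sample; median-of-ratios "
            "reference is undefined (pseudo-reference fallback is disabled)"
        )
    ref = counts[all_positive]
    log_geomean = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_geomean)
    sf = np.median(ratios, axis=0)
    return pd.Series(sf, index=cm.sample_ids, name="size_factor")


def normalized_counts(cm: CountMatrix, sf: pd.Series | None = None) -> pd.DataFrame:
    """Counts divided by per-sample size factors."""
    if sf is None:
        sf = size_factors(cm)
    return cm.counts / sf.loc[cm.sample_ids].to_numpy()


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    ``padj_(i) = min_{j >= i}( m * p_(j) / j )`` over the sorted p-values,
    capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    # padj >= p holds mathematically; enforce it against float rounding
    return np.maximum(out, p)


def wald_test(
    cm: CountMatrix,
    meta: SampleMetadata,
    contrast: tuple[str, str] = ("tumour", "control"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature two-group Wald test on NB counts.

    The log2 fold change is ``log2((mean_norm_a + 0.5) / (mean_norm_b +
    0.5))`` for ``contrast = (a, b)``.  Its standard error comes from the
    delta method under ``Var(count) = mu + dispersion * mu^2`` with a
    per-feature method-of-moments dispersion pooled across groups and
    floored at :data:`MIN_DISPERSION`.

    Returns a DataFrame with columns :data:`RESULT_COLUMNS`; ``padj`` is
    BH over all retained features and ``significant`` is ``padj < alpha``.
    """
    meta.check_matches(cm)
    group_a, group_b = contrast
    samples_a = meta.group_samples(group_a)
    samples_b = meta.group_samples(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each contrast group needs at least 2 samples")

    norm = normalized_counts(cm)
    ya = norm[samples_a].to_numpy()
    yb = norm[samples_b].to_numpy()
    na, nb = ya.shape[1], yb.shape[1]

    mu_a, mu_b = ya.mean(axis=1), yb.mean(axis=1)
    var_a, var_b = ya.var(axis=1, ddof=1), yb.var(axis=1, ddof=1)

    # pooled method-of-moments dispersion: Var = mu + alpha * mu^2
    num = (na - 1) * (var_a - mu_a) + (nb - 1) * (var_b - mu_b)
    den = (na - 1) * mu_a**2 + (nb - 1) * mu_b**2
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(den > 0, num / den, 0.0)
    disp = np.maximum(disp, MIN_DISPERSION)

    log2fc = np.log2((mu_a + PSEUDO) / (mu_b + PSEUDO))
    v_a = (mu_a + disp * mu_a**2) / na
    v_b = (mu_b + disp * mu_b**2) / nb
    se = np.sqrt(v_a / (mu_a + PSEUDO) ** 2 + v_b / (mu_b + PSEUDO) ** 2) / LN2

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    padj = bh_adjust(p)

    return pd.DataFrame(
        {
            "feature_id": cm.feature_ids,
            "base_mean": norm.mean(axis=1).to_numpy(),
            "log2fc": log2fc,
            "se": se,
            "p": p,
            "padj": padj,
            "significant": padj < alpha,
        }
    )
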