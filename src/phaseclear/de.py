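"""Negative-binomial two-group differential expression.

The recognizable core of the standard RNA-seq workflow is implemented
directly: median-of-ratios size factors, an NB mean-dispersion variance model
(Var = mu + alpha * mu^2), a Wald test on the log2 fold change of normalized
group means, and Benjamini-Hochberg FDR.  DEGs are genes with adjusted
p < max_fdr and |fold change| > min_fc, both strict.

Dispersion is estimated per gene by method of moments within groups; because
a handful of replicates leaves those estimates with very few residual degrees
of freedom, the pipeline-facing estimator shrinks them toward a binned
mean-dispersion trend before testing (see :func:`moderate_dispersion`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CountMatrix
from .errors import ValidationError

DISPERSION_FLOOR = 1e-8

RESULT_COLUMNS = ("base_mean", "log2fc", "se", "wald_stat", "p_value", "padj")


@dataclass(frozen=True)
class DEThresholds:
    """DEG membership: padj < max_fdr and |fold change| > min_fc (strict)."""

    max_fdr: float = 0.05
    min_fc: float = 1.5

    def __post_init__(self) -> None:
        if not (0.0 < self.max_fdr < 1.0):
            raise ValidationError(f"max_fdr must be in (0, 1), got {self.max_fdr}")
        if self.min_fc <= 1.0:
            raise ValidationError(f"min_fc must be > 1, got {self.min_fc}")


# -- normalization ----------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-gene geometric mean over genes with no zero
    count; each sample's factor is the median ratio of its counts to that
    reference.
    """
    arr = counts.to_numpy(dtype=float)
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        raise ValidationError(
            "no gene has nonzero counts in every sample; cannot form the "
            "median-of-ratios reference (consider a pseudo-reference fallback)"
        )
    logs = np.log(arr[allpos])
    log_geomean = logs.mean(axis=1)
    sf = np.exp(np.median(logs - log_geomean[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, sf: pd.Series) -> pd.DataFrame:
    if (sf <= 0).any():
        raise ValidationError("size factors must be positive")
    return counts / sf.reindex(counts.columns)


# -- dispersion -------------------------------------------------------------

def _group_labels(columns: pd.Index, groups: Mapping) -> pd.Series:
    labels = pd.Series({c: groups[c] for c in columns})
    return labels


def _pooled_moments(norm: pd.DataFrame, groups: Mapping) -> Tuple[pd.Series, pd.Series, int]:
    """Grand mean, pooled within-group variance, residual df."""
    labels = _group_labels(norm.columns, groups)
    ss = pd.Series(0.0, index=norm.index)
    k = labels.nunique()
    for label in labels.unique():
        cols = labels.index[labels == label]
        if len(cols) < 2:
            raise ValidationError(
                f"group {label!r} has {len(cols)} sample(s); >= 2 required "
                f"for dispersion estimation"
            )
        sub = norm[cols]
        ss += ((sub.sub(sub.mean(axis=1), axis=0)) ** 2).sum(axis=1)
    df = norm.shape[1] - k
    variance = ss / df
    mean = norm.mean(axis=1)
    return mean, variance, df


def dispersion_mom(
    norm_counts: pd.DataFrame, groups: Mapping, floor: float = DISPERSION_FLOOR
) -> pd.Series:
    """Per-gene method-of-moments NB dispersion, floored.

    alpha = max((pooled within-group variance - mean) / mean^2, floor);
    degenerate genes (zero mean) receive the floor.
    """
    mean, variance, _ = _pooled_moments(norm_counts, groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (variance - mean) / mean**2
    alpha = raw.where(mean > 0, floor).clip(lower=floor)
    return alpha.rename("alpha")


def fit_dispersion_trend(
    norm_counts: pd.DataFrame,
    groups: Mapping,
    n_bins: int = 20,
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Binned mean-dispersion trend.

    Genes are binned by expression rank; each bin's trend value is the mean
    of the *unfloored* moment estimates (unbiased for the common dispersion
    of the bin), clipped at the floor.  Genes with zero mean inherit the
    global trend median.
    """
    mean, variance, _ = _pooled_moments(norm_counts, groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (variance - mean) / mean**2
    expressed = mean > 0
    trend = pd.Series(floor, index=norm_counts.index, name="alpha_trend")
    if expressed.sum() == 0:
        return trend
    ranks = mean[expressed].rank(method="first")
    n_bins = max(1, min(n_bins, int(expressed.sum() // 25) or 1))
    bins = np.ceil(ranks / (len(ranks) / n_bins)).clip(1, n_bins).astype(int)
    bin_values = raw[expressed].groupby(bins).mean().clip(lower=floor)
    trend[expressed] = bins.map(bin_values).to_numpy()
    trend[~expressed] = float(np.median(bin_values))
    return trend


def moderate_dispersion(
    norm_counts: pd.DataFrame,
    groups: Mapping,
    prior_df: float = 20.0,
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Shrink per-gene moment estimates toward the mean-dispersion trend.

    Log-scale weighted blend with weight df / (df + prior_df) on the per-gene
    estimate, where df is the pooled residual degrees of freedom.  With two
    replicates per group the per-gene weight is small and the estimate is
    dominated by the trend, which is what keeps the Wald reference
    distribution close to normal.
    """
    mean, variance, df = _pooled_moments(norm_counts, groups)
    trend = fit_dispersion_trend(norm_counts, groups, floor=floor)
    gene = dispersion_mom(norm_counts, groups, floor=floor)
    # avoid -inf leverage from floored per-gene estimates
    gene = np.maximum(gene, trend / 50.0)
    w = df / (df + prior_df)
    alpha = np.exp(w * np.log(gene) + (1.0 - w) * np.log(trend))
    return pd.Series(alpha, index=norm_counts.index, name="alpha")


# -- testing ----------------------------------------------------------------

def nb_wald_test(
    counts: pd.DataFrame,
    sf: pd.Series,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: pd.Series,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Wald test of group B vs group A on normalized means.

    log2fc = log2((mean_B + c) / (mean_A + c)) with pseudocount c; the
    standard error comes from the delta method under NB(mu, alpha) per
    sample.  Genes with all-zero counts, and any test with a
    single-replicate group, carry NaN p-values (log2fc is still reported).
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValidationError("both groups must be non-empty")
    sf = sf.reindex(group_a + group_b)
    if sf.isna().any() or (sf <= 0).any():
        raise ValidationError("size factors must be positive for every tested sample")
    norm = counts[group_a + group_b] / sf
    m_a = norm[group_a].mean(axis=1)
    m_b = norm[group_b].mean(axis=1)
    alpha = alpha.reindex(counts.index).astype(float)
    c = pseudocount

    log2fc = np.log2((m_b + c) / (m_a + c))

    def mean_variance(m: pd.Series, cols: Sequence[str]) -> pd.Series:
        inv_sf = (1.0 / sf[cols]).sum()
        n = len(cols)
        # Var(norm_i) = mu/sf_i + alpha*mu^2 per sample, mu estimated by m
        return (m * inv_sf + alpha * m**2 * n) / n**2

    var_a = mean_variance(m_a, group_a)
    var_b = mean_variance(m_b, group_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        se_ln = np.sqrt(var_a / (m_a + c) ** 2 + var_b / (m_b + c) ** 2)
    se = se_ln / np.log(2.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        wald = log2fc / se
    wald = wald.where(se > 0)
    wald = wald.where(~((log2fc == 0) & (se > 0)), 0.0)
    p = pd.Series(2.0 * stats.norm.sf(np.abs(wald)), index=counts.index)
    p = p.where(se > 0)

    if len(group_a) < 2 or len(group_b) < 2:
        p[:] = np.nan

    result = pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1),
            "log2fc": log2fc,
            "se": se.where(se > 0),
            "wald_stat": wald,
            "p_value": p,
            "padj": bh_adjust(p),
        }
    )
    return result


def bh_adjust(p_values) -> pd.Series:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through.

    padj_(i) = min_{j >= i} p_(j) * m / j over the m non-missing values,
    capped at 1, returned in the original order.
    """
    p = pd.Series(p_values, dtype=float)
    valid = p.notna()
    vals = p[valid].to_numpy()
    if ((vals < 0) | (vals > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(vals)
    adjusted = np.full(len(p), np.nan)
    if m:
        order = np.argsort(vals, kind="stable")
        ranked = vals[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        ranked = np.minimum(ranked, 1.0)
        out = np.empty(m)
        out[order] = ranked
        adjusted[np.flatnonzero(valid.to_numpy())] = out
    return pd.Series(adjusted, index=p.index, name="padj")


def call_degs(
    result: pd.DataFrame, thresholds: DEThresholds = DEThresholds()
) -> Tuple[frozenset, frozenset]:
    """(up, down) DEG sets under strict padj and fold-change cuts.

    Convention: group A is the earlier stage (or control) and group B the
    later stage (or knockout), so membership in ``down`` means the gene is
    lower in B than in A.
    """
    lfc_cut = np.log2(thresholds.min_fc)
    sig = result["padj"] < thresholds.max_fdr
    up = frozenset(result.index[sig & (result["log2fc"] > lfc_cut)])
    down = frozenset(result.index[sig & (result["log2fc"] < -lfc_cut)])
    return up, down


def de_contrast(
    cm: CountMatrix,
    *,
    factor: str,
    level_a: str,
    level_b: str,
    where: Optional[Mapping] = None,
    prior_df: float = 20.0,
    thresholds: Optional[DEThresholds] = None,
) -> pd.DataFrame:
    """End-to-end contrast on a metadata factor within an optional selection.

    Runs size factors, moderated dispersion and the Wald test on the samples
    selected by ``where`` whose ``factor`` equals ``level_a`` (reference) or
    ``level_b``.  When ``thresholds`` is given a ``call`` column
    (up / down / ns) is appended.
    """
    criteria = dict(where or {})
    sub = cm.select_samples(**criteria)
    meta = sub.samples
    if factor not in meta.columns:
        raise ValidationError(f"unknown contrast factor {factor!r}")
    cols_a = list(meta.index[meta[factor] == level_a])
    cols_b = list(meta.index[meta[factor] == level_b])
    if not cols_a or not cols_b:
        raise ValidationError(
            f"contrast {factor}:{level_a}:{level_b} has an empty group "
            f"under selection {criteria!r}"
        )
    counts = sub.counts[cols_a + cols_b]
    sf = size_factors(counts)
    norm = normalized_counts(counts, sf)
    groups = {c: ("A" if c in set(cols_a) else "B") for c in counts.columns}
    if len(cols_a) >= 2 and len(cols_b) >= 2:
        alpha = moderate_dispersion(norm, groups, prior_df=prior_df)
    else:
        alpha = pd.Series(DISPERSION_FLOOR, index=counts.index)
    result = nb_wald_test(counts, sf, cols_a, cols_b, alpha)
    if thresholds is not None:
        up, down = call_degs(result, thresholds)
        call = pd.Series("ns", index=result.index)
        call[list(up)] = "up"
        call[list(down)] = "down"
        result["call"] = call
    return result
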