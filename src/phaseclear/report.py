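"""Summary statistics and the machine-readable run report.

Includes the relative stability change (the genotype difference of
cross-stage log2 fold changes), empirical CDFs, a Mann-Whitney U test (exact
by enumeration for small samples, tie- and continuity-corrected normal
approximation otherwise), and the DEG fold-increase statistic.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix
from .errors import ValidationError
from .quantify import group_mean

EXACT_LIMIT = 12  # enumerate the permutation null up to this pooled size


def stability_change(
    expr: ExpressionMatrix,
    transition,
    pseudocount: float = 0.1,
    assay: str = "rna",
    groups: Optional[Mapping[str, Iterable]] = None,
) -> pd.DataFrame:
    """Per-gene relative stability change between knockout and control.

    delta = log2((mean_vKO,later + c) / (mean_vKO,earlier + c))
          - log2((mean_ctrl,later + c) / (mean_ctrl,earlier + c))

    A positive delta means the transcript is more stable (persists longer)
    across the transition in the knockout than in control.  ``groups`` maps
    labels to gene sets; unlisted genes get the label ``"other"``.
    """
    earlier, later = transition
    c = pseudocount
    delta = None
    logfc = {}
    for genotype in ("control", "vKO"):
        m_e = group_mean(expr, genotype=genotype, stage=earlier, assay=assay)
        m_l = group_mean(expr, genotype=genotype, stage=later, assay=assay)
        logfc[genotype] = np.log2((m_l + c) / (m_e + c))
    delta = (logfc["vKO"] - logfc["control"]).rename("delta")

    label = pd.Series("other", index=delta.index, name="group")
    for name, genes in (groups or {}).items():
        members = delta.index.intersection(list(genes))
        label[members] = name
    return pd.DataFrame({"delta": delta, "group": label})


def ecdf(values: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF sample points.

    Returns (sorted unique values, cumulative fractions in (0, 1]); repeated
    values collapse into a single step of proportionally larger height.
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValidationError("ecdf requires at least one finite value")
    xs, counts = np.unique(arr, return_counts=True)
    return xs, np.cumsum(counts) / arr.size


class MannWhitneyResult(NamedTuple):
    statistic: float  # U of the first sample
    p_value: float
    method: str  # "exact" | "normal"


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_limit: int = EXACT_LIMIT,
) -> MannWhitneyResult:
    """Mann-Whitney U test of x versus y.

    U counts pairs with x_i > y_j plus half the ties.  For pooled sizes up to
    ``exact_limit`` the permutation null is enumerated exactly (ties
    included); otherwise the normal approximation with tie and continuity
    corrections is used.  ``alternative`` in {"two-sided", "greater",
    "less"}; "greater" tests a rightward shift of x.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must contain at least one value")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    n1, n2 = x.size, y.size
    u_obs = _u_statistic(x, y)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= exact_limit:
        pooled = np.concatenate([x, y])
        comp = (pooled[:, None] > pooled[None, :]) + 0.5 * (
            pooled[:, None] == pooled[None, :]
        )
        np.fill_diagonal(comp, 0.0)
        us = []
        idx = np.arange(n1 + n2)
        for subset in itertools.combinations(idx, n1):
            rest = np.setdiff1d(idx, subset, assume_unique=True)
            us.append(comp[np.ix_(subset, rest)].sum())
        us = np.asarray(us)
        eps = 1e-9
        if alternative == "two-sided":
            p = float(np.mean(np.abs(us - mu) >= abs(u_obs - mu) - eps))
        elif alternative == "greater":
            p = float(np.mean(us >= u_obs - eps))
        else:
            p = float(np.mean(us <= u_obs + eps))
        return MannWhitneyResult(u_obs, min(p, 1.0), "exact")

    # normal approximation with tie correction
    pooled = np.concatenate([x, y])
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return MannWhitneyResult(u_obs, 1.0, "normal")
    sigma = math.sqrt(sigma2)
    if alternative == "two-sided":
        z = (abs(u_obs - mu) - 0.5) / sigma
        p = 2.0 * stats.norm.sf(max(z, 0.0))
    elif alternative == "greater":
        z = (u_obs - mu - 0.5) / sigma
        p = stats.norm.sf(z)
    else:
        z = (u_obs - mu + 0.5) / sigma
        p = stats.norm.cdf(z)
    return MannWhitneyResult(u_obs, float(min(p, 1.0)), "normal")


def fold_increase(count_earlier: int, count_later: int) -> float:
    """Relative increase (later - earlier) / earlier; NaN for a zero baseline."""
    if count_earlier < 0 or count_later < 0:
        raise ValidationError("counts must be non-negative")
    if count_earlier == 0:
        return float("nan")
    return (count_later - count_earlier) / count_earlier


# -- report -----------------------------------------------------------------

@dataclass
class SummaryReport:
    """JSON-serializable run summary; equality is structural."""

    data: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.data, indent=2, sort_keys=True, allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "SummaryReport":
        if hasattr(source, "read"):
            return cls(json.load(source))
        try:
            with open(source) as fh:
                return cls(json.load(fh))
        except (OSError, TypeError):
            return cls(json.loads(source))

    def __eq__(self, other) -> bool:
        return isinstance(other, SummaryReport) and self.data == other.data


def _round_sig(p: float, digits: int = 3) -> float:
    if p is None or not np.isfinite(p) or p == 0:
        return p
    return float(f"{p:.{digits}g}")


def build_report(
    *,
    transition,
    thresholds: Mapping,
    rip_call,
    de_counts: Mapping[str, int],
    classification,
    overlaps: Mapping[str, "OverlapLike"] = None,
    stability_test: Optional[Mapping] = None,
    genotype_deg_counts: Optional[Mapping[str, Mapping[str, int]]] = None,
    deg_fold_increase: Optional[Mapping] = None,
    truth_eval: Optional[Mapping] = None,
    seed: Optional[int] = None,
    config_digest: Optional[str] = None,
) -> SummaryReport:
    """Assemble the serializable run summary.

    Counts are copied from the upstream objects (so report consistency with
    them is structural); percents are rounded to two decimals, fold
    increases to one, p-values to three significant figures.
    """
    n_targets_m6a = None
    data = {
        "transition": list(transition),
        "thresholds": dict(thresholds),
        "seed": seed,
        "config_digest": config_digest,
        "rip": {
            "per_replicate_counts": {
                str(r): int(n) for r, n in rip_call.replicate_counts.items()
            },
            "n_final_targets": len(rip_call.final_targets),
            "replicate_correlation": _round_sig(rip_call.correlation, 4),
        },
        "de": {k: int(v) for k, v in de_counts.items()},
        "decay": {k: int(v) for k, v in classification.counts.items()},
    }
    if overlaps:
        data["overlaps"] = {
            name: {
                "numerator": int(ov.numerator),
                "denominator": int(ov.denominator),
                "percent": round(float(ov.percent), 2),
            }
            for name, ov in overlaps.items()
        }
    if stability_test is not None:
        data["stability"] = {
            key: (_round_sig(val) if key.endswith("p") else val)
            for key, val in stability_test.items()
        }
    if genotype_deg_counts is not None:
        data["genotype_degs_per_stage"] = {
            stage: {k: int(v) for k, v in counts.items()}
            for stage, counts in genotype_deg_counts.items()
        }
    if deg_fold_increase is not None:
        value = deg_fold_increase.get("value")
        data["deg_fold_increase"] = {
            **deg_fold_increase,
            "value": (round(float(value), 1) if value is not None and np.isfinite(value) else None),
        }
    if truth_eval is not None:
        data["truth_eval"] = {k: float(v) for k, v in truth_eval.items()}
    return SummaryReport(data)
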