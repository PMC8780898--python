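"""RIP-seq target calling: per-replicate IP/Input enrichment and intersection.

A transcript is called bound in one replicate when its Input FPKM exceeds the
input floor AND its IP/Input FPKM ratio exceeds the enrichment threshold
(both strict, matching the rule "Input FPKM >1 and IP FPKM / Input FPKM
>1.2"); the final target set is the intersection across replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix
from .errors import ValidationError


@dataclass(frozen=True)
class RipThresholds:
    """Strict lower bounds on Input FPKM and the IP/Input FPKM ratio."""

    min_input_fpkm: float = 1.0
    min_ip_input_ratio: float = 1.2

    def __post_init__(self) -> None:
        if self.min_input_fpkm <= 0 or self.min_ip_input_ratio <= 0:
            raise ValidationError("RIP thresholds must be positive")


@dataclass
class RipCall:
    """Per-replicate target sets, their intersection, and QC."""

    replicate_targets: Dict[int, frozenset]
    final_targets: frozenset
    thresholds: RipThresholds
    replicate_counts: Dict[int, int] = field(default_factory=dict)
    correlation: float = float("nan")

    def __post_init__(self) -> None:
        for rep, genes in self.replicate_targets.items():
            if not self.final_targets <= genes:
                raise ValidationError(
                    f"final targets are not a subset of replicate {rep} targets"
                )
        if not self.replicate_counts:
            self.replicate_counts = {r: len(g) for r, g in self.replicate_targets.items()}


def call_rip_replicate(
    input_fpkm: pd.Series, ip_fpkm: pd.Series, thresholds: RipThresholds = RipThresholds()
) -> frozenset:
    """Genes passing the enrichment predicate in a single replicate."""
    if not input_fpkm.index.equals(ip_fpkm.index):
        raise ValidationError("IP and Input vectors are not aligned on the same genes")
    inp = input_fpkm.to_numpy(dtype=float)
    ip = ip_fpkm.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(inp > 0, ip / np.where(inp > 0, inp, 1.0), np.nan)
    passed = (inp > thresholds.min_input_fpkm) & (ratio > thresholds.min_ip_input_ratio)
    return frozenset(input_fpkm.index[passed])


def final_targets(replicate_sets: Sequence[Iterable]) -> frozenset:
    """Intersection across replicate target sets (defined on >= 2 replicates)."""
    sets = [frozenset(s) for s in replicate_sets]
    if len(sets) < 2:
        raise ValidationError(
            f"final targets require >= 2 replicate sets, got {len(sets)}"
        )
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out


def replicate_correlation(
    expr_rep1: pd.Series, expr_rep2: pd.Series, pseudocount: float = 0.1
) -> float:
    """Spearman rank correlation between replicates on log10(FPKM + pseudocount).

    Constant vectors make the coefficient undefined; NaN is returned rather
    than raising.
    """
    if not expr_rep1.index.equals(expr_rep2.index):
        raise ValidationError("replicate vectors are not aligned on the same genes")
    if len(expr_rep1) < 3:
        raise ValidationError("replicate correlation requires >= 3 genes")
    x = np.log10(expr_rep1.to_numpy(dtype=float) + pseudocount)
    y = np.log10(expr_rep2.to_numpy(dtype=float) + pseudocount)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def call_targets(
    expr: ExpressionMatrix,
    *,
    genotype: str = "control",
    stage: str,
    thresholds: RipThresholds = RipThresholds(),
) -> RipCall:
    """Call final YTHDF2 targets from the paired RIP libraries of one condition."""
    sub = expr.samples[
        (expr.samples["genotype"] == genotype) & (expr.samples["stage"] == stage)
    ]
    replicates = sorted(sub.loc[sub["assay"] == "rip_ip", "replicate"].unique())
    per_replicate: Dict[int, frozenset] = {}
    ip_columns = []
    for rep in replicates:
        ip_cols = sub.index[(sub["assay"] == "rip_ip") & (sub["replicate"] == rep)]
        inp_cols = sub.index[(sub["assay"] == "rip_input") & (sub["replicate"] == rep)]
        if len(ip_cols) != 1 or len(inp_cols) != 1:
            raise ValidationError(
                f"replicate {rep} of ({genotype}, {stage}) lacks a unique IP/Input pair"
            )
        per_replicate[int(rep)] = call_rip_replicate(
            expr.fpkm[inp_cols[0]], expr.fpkm[ip_cols[0]], thresholds
        )
        ip_columns.append(ip_cols[0])
    if len(per_replicate) < 2:
        raise ValidationError(
            f"target calling for ({genotype}, {stage}) requires >= 2 RIP replicates, "
            f"found {len(per_replicate)}"
        )
    corr = replicate_correlation(expr.fpkm[ip_columns[0]], expr.fpkm[ip_columns[1]])
    return RipCall(
        replicate_targets=per_replicate,
        final_targets=final_targets(list(per_replicate.values())),
        thresholds=thresholds,
        correlation=corr,
    )
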