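"""Four-criteria classification of delayed-decay transcripts.

A transcript is *degraded* when it is (1) significantly down-regulated
across the wild-type stage transition, (2) m6A-modified at the earlier
stage, and (3) a final YTHDF2 RIP target.  It shows *delayed decay* when, in
addition, (4) its expression has an up-tendency (fold change > 1.2, strict)
across the same transition in the knockout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Optional

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix
from .errors import ValidationError
from .quantify import group_mean

DEFAULT_KO_FC_THRESHOLD = 1.2
DEFAULT_FC_PSEUDOCOUNT = 0.1


class OverlapFraction(NamedTuple):
    """|deg_set ∩ targets ∩ m6a| over |deg_set| as a rounded percent."""

    numerator: int
    denominator: int
    percent: float


@dataclass
class DecayClassification:
    """Per-gene criteria ledger plus the derived degraded / delayed sets."""

    table: pd.DataFrame  # columns c1_down, c2_m6a, c3_target, c4_ko_up, label
    degraded: frozenset
    delayed: frozenset

    def __post_init__(self) -> None:
        if not (self.delayed <= self.degraded):
            raise ValidationError("delayed set must be a subset of the degraded set")

    @property
    def counts(self) -> Mapping[str, int]:
        return {"degraded": len(self.degraded), "delayed": len(self.delayed)}


def _as_set(genes: Iterable, universe: Optional[pd.Index], name: str) -> frozenset:
    s = frozenset(genes)
    if universe is not None:
        stray = s - set(universe)
        if stray:
            raise ValidationError(
                f"{name} contains gene(s) outside the gene universe: "
                f"{sorted(stray)[:5]}"
            )
    return s


def degraded_m6a_targets(
    down_set: Iterable,
    m6a_prev: Iterable,
    targets: Iterable,
    universe: Optional[pd.Index] = None,
) -> frozenset:
    """down ∩ m6A(earlier stage) ∩ targets: the degraded m6A-marked targets."""
    down = _as_set(down_set, universe, "down_set")
    m6a = _as_set(m6a_prev, universe, "m6a_prev")
    tgt = _as_set(targets, universe, "targets")
    return down & m6a & tgt


def ko_fold_change(
    expr: ExpressionMatrix,
    transition,
    genotype: str = "vKO",
    pseudocount: float = DEFAULT_FC_PSEUDOCOUNT,
    assay: str = "rna",
) -> pd.Series:
    """Per-gene (later + c) / (earlier + c) mean-FPKM fold change within a genotype."""
    earlier, later = transition
    m_earlier = group_mean(expr, genotype=genotype, stage=earlier, assay=assay)
    m_later = group_mean(expr, genotype=genotype, stage=later, assay=assay)
    fc = (m_later + pseudocount) / (m_earlier + pseudocount)
    return fc.rename("ko_fc")


def delayed_decay_set(
    degraded: Iterable, ko_fc: pd.Series, threshold: float = DEFAULT_KO_FC_THRESHOLD
) -> frozenset:
    """Degraded genes whose knockout fold change exceeds the threshold (strict)."""
    degraded = frozenset(degraded)
    missing = degraded - set(ko_fc.index)
    if missing:
        raise ValidationError(
            f"degraded gene(s) missing from the fold-change vector: {sorted(missing)[:5]}"
        )
    return frozenset(g for g in degraded if ko_fc[g] > threshold)


def overlap_fraction(deg_set: Iterable, targets: Iterable, m6a: Iterable) -> OverlapFraction:
    """Fraction of a DEG set that is both reader-bound and m6A-modified."""
    deg = frozenset(deg_set)
    numerator = len(deg & frozenset(targets) & frozenset(m6a))
    denominator = len(deg)
    percent = round(100.0 * numerator / denominator, 2) if denominator else 0.0
    return OverlapFraction(numerator, denominator, percent)


def classify(
    universe: pd.Index,
    *,
    down_set: Iterable,
    m6a_prev: Iterable,
    targets: Iterable,
    ko_fc: pd.Series,
    threshold: float = DEFAULT_KO_FC_THRESHOLD,
) -> DecayClassification:
    """Evaluate the four criteria over the whole gene universe."""
    down = _as_set(down_set, universe, "down_set")
    m6a = _as_set(m6a_prev, universe, "m6a_prev")
    tgt = _as_set(targets, universe, "targets")
    missing = set(universe) - set(ko_fc.index)
    if missing:
        raise ValidationError(
            f"fold-change vector lacks gene(s) of the universe: {sorted(missing)[:5]}"
        )
    fc = ko_fc.reindex(universe)

    table = pd.DataFrame(index=universe)
    table["c1_down"] = table.index.isin(down)
    table["c2_m6a"] = table.index.isin(m6a)
    table["c3_target"] = table.index.isin(tgt)
    table["c4_ko_up"] = (fc > threshold).to_numpy()

    degraded_mask = table["c1_down"] & table["c2_m6a"] & table["c3_target"]
    delayed_mask = degraded_mask & table["c4_ko_up"]
    label = pd.Series("none", index=universe)
    label[degraded_mask] = "degraded_only"
    label[delayed_mask] = "delayed"
    table["label"] = label

    return DecayClassification(
        table=table,
        degraded=frozenset(universe[degraded_mask]),
        delayed=frozenset(universe[delayed_mask]),
    )
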