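"""End-to-end pipeline: FPKM -> RIP targets -> DE -> decay classes -> report."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from . import de as de_mod
from . import decay, report, rip, simulate
from .config import SimConfig
from .datatypes import CountMatrix, ExpressionMatrix
from .errors import ValidationError
from .quantify import compute_fpkm


@dataclass
class PipelineResult:
    expr: ExpressionMatrix
    rip_call: rip.RipCall
    de_result: pd.DataFrame
    up_set: frozenset
    down_set: frozenset
    ko_fc: pd.Series
    classification: decay.DecayClassification
    stability: pd.DataFrame
    summary: report.SummaryReport


def run_pipeline(
    cm: CountMatrix,
    m6a_prev: Iterable,
    *,
    transition: Tuple[str, str],
    rip_genotype: str = "control",
    rip_stage: Optional[str] = None,
    rip_thresholds: rip.RipThresholds = rip.RipThresholds(),
    de_thresholds: de_mod.DEThresholds = de_mod.DEThresholds(),
    ko_fc_threshold: float = decay.DEFAULT_KO_FC_THRESHOLD,
    stage_deg_counts: bool = False,
    truth: Optional[pd.DataFrame] = None,
    seed: Optional[int] = None,
    config_digest: Optional[str] = None,
) -> PipelineResult:
    """Run the full delayed-decay analysis on one dataset.

    ``transition`` is the (earlier, later) stage pair.  RIP targets are
    called from the paired IP/Input libraries of ``rip_genotype`` at
    ``rip_stage`` (default: the earlier transition stage, where the decaying
    transcripts are still expressed).  ``m6a_prev`` is the external gene list
    of m6A-marked genes at the earlier stage.
    """
    earlier, later = transition
    expr = compute_fpkm(cm)
    universe = expr.gene_ids

    m6a_prev = frozenset(m6a_prev)
    stray = m6a_prev - set(universe)
    if stray:
        raise ValidationError(
            f"m6A gene list contains gene(s) outside the dataset: {sorted(stray)[:5]}"
        )

    rip_call = rip.call_targets(
        expr,
        genotype=rip_genotype,
        stage=rip_stage or earlier,
        thresholds=rip_thresholds,
    )

    de_result = de_mod.de_contrast(
        cm,
        factor="stage",
        level_a=earlier,
        level_b=later,
        where={"genotype": "control", "assay": "rna"},
        thresholds=de_thresholds,
    )
    up_set, down_set = de_mod.call_degs(de_result, de_thresholds)

    ko_fc = decay.ko_fold_change(expr, transition, genotype="vKO")
    classification = decay.classify(
        universe,
        down_set=down_set,
        m6a_prev=m6a_prev,
        targets=rip_call.final_targets,
        ko_fc=ko_fc,
        threshold=ko_fc_threshold,
    )

    bound_marked = m6a_prev & rip_call.final_targets
    stability = report.stability_change(
        expr, transition, groups={"m6A+target": bound_marked}
    )
    focal = stability.loc[stability["group"] == "m6A+target", "delta"]
    other = stability.loc[stability["group"] == "other", "delta"]
    if len(focal) and len(other):
        two_sided = report.mann_whitney(focal, other, alternative="two-sided")
        greater = report.mann_whitney(focal, other, alternative="greater")
        stability_test = {
            "n_m6a_target": int(len(focal)),
            "n_other": int(len(other)),
            "mw_U": float(two_sided.statistic),
            "two_sided_p": two_sided.p_value,
            "greater_p": greater.p_value,
        }
    else:
        stability_test = {"n_m6a_target": int(len(focal)), "n_other": int(len(other))}

    overlaps = {
        "down": decay.overlap_fraction(down_set, rip_call.final_targets, m6a_prev),
        "up": decay.overlap_fraction(up_set, rip_call.final_targets, m6a_prev),
    }

    genotype_deg_counts = None
    deg_fold_increase = None
    if stage_deg_counts:
        genotype_deg_counts = {}
        stages = list(dict.fromkeys(cm.samples["stage"]))
        for stage in stages:
            res = de_mod.de_contrast(
                cm,
                factor="genotype",
                level_a="control",
                level_b="vKO",
                where={"stage": stage, "assay": "rna"},
            )
            g_up, g_down = de_mod.call_degs(res, de_thresholds)
            genotype_deg_counts[stage] = {"n_up": len(g_up), "n_down": len(g_down)}
        last = stages[-1]
        n_later_stage = sum(genotype_deg_counts[later].values())
        n_last = sum(genotype_deg_counts[last].values())
        deg_fold_increase = {
            "from_stage": later,
            "to_stage": last,
            "from_count": n_later_stage,
            "to_count": n_last,
            "value": report.fold_increase(n_later_stage, n_last)
            if n_later_stage
            else None,
        }

    truth_eval = None
    if truth is not None:
        sens, fdp = evaluate_against_truth(classification.delayed, truth)
        truth_eval = {"sensitivity": sens, "fdp": fdp}

    summary = report.build_report(
        transition=transition,
        thresholds={
            "min_input_fpkm": rip_thresholds.min_input_fpkm,
            "min_ip_input_ratio": rip_thresholds.min_ip_input_ratio,
            "max_fdr": de_thresholds.max_fdr,
            "min_fc": de_thresholds.min_fc,
            "ko_fc_threshold": ko_fc_threshold,
        },
        rip_call=rip_call,
        de_counts={
            "n_down": len(down_set),
            "n_up": len(up_set),
            "n_targets_m6a": len(bound_marked),
        },
        classification=classification,
        overlaps=overlaps,
        stability_test=stability_test,
        genotype_deg_counts=genotype_deg_counts,
        deg_fold_increase=deg_fold_increase,
        truth_eval=truth_eval,
        seed=seed,
        config_digest=config_digest,
    )
    return PipelineResult(
        expr=expr,
        rip_call=rip_call,
        de_result=de_result,
        up_set=up_set,
        down_set=down_set,
        ko_fc=ko_fc,
        classification=classification,
        stability=stability,
        summary=summary,
    )


def run_synthetic(config: SimConfig, **pipeline_kwargs) -> Tuple[PipelineResult, pd.DataFrame]:
    """Simulate a dataset under ``config`` and run the pipeline on it."""
    cm, truth = simulate.simulate_dataset(config)
    m6a_prev = simulate.m6a_genes(truth, config.focal_transition[0])
    result = run_pipeline(
        cm,
        m6a_prev,
        transition=config.focal_transition,
        truth=truth,
        seed=config.seed,
        config_digest=config.digest(),
        **pipeline_kwargs,
    )
    return result, truth


def evaluate_against_truth(called: Iterable, truth: pd.DataFrame) -> Tuple[float, float]:
    """(sensitivity, false-discovery proportion) against planted cleared_target genes."""
    called = frozenset(called)
    planted = frozenset(truth.index[truth["gene_class"] == "cleared_target"])
    sensitivity = len(called & planted) / len(planted) if planted else float("nan")
    fdp = len(called - planted) / len(called) if called else 0.0
    return sensitivity, fdp
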