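"""Stability change, ECDF, Mann-Whitney, fold increase, report round trip."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from phaseclear import SummaryReport, ecdf, fold_increase, mann_whitney, stability_change
from phaseclear.errors import ValidationError

from conftest import make_count_matrix
from phaseclear import compute_fpkm


def _expr_two_genotypes(ctrl_dsg, ctrl_ps, ko_dsg, ko_ps):
    lib = 1_000_000

    def col(fpkm_value):
        c0 = int(round(fpkm_value * lib * 1000 / 1e9))
        return [c0, lib - c0]

    meta, cols = {}, {}
    for genotype, dsg, ps in [("control", ctrl_dsg, ctrl_ps), ("vKO", ko_dsg, ko_ps)]:
        for stage, value in [("DSG", dsg), ("PS", ps)]:
            sid = f"{genotype}_{stage}"
            cols[sid] = col(value)
            meta[sid] = (genotype, stage, 1, "rna")
    cm = make_count_matrix(cols, sample_meta=meta, lengths=[1000, 1000])
    return compute_fpkm(cm)


def test_stability_change_hand_arithmetic():
    # control 80 -> 20, knockout 80 -> 80: delta = 0 - (-2) = +2
    expr = _expr_two_genotypes(80, 20, 80, 80)
    table = stability_change(expr, ("DSG", "PS"))
    assert table.loc["g0", "delta"] == pytest.approx(2.0, abs=0.02)
    # identical programs in both genotypes -> delta 0 everywhere
    null = stability_change(_expr_two_genotypes(40, 10, 40, 10), ("DSG", "PS"))
    np.testing.assert_allclose(null["delta"], 0.0, atol=1e-9)


def test_stability_change_antisymmetric_under_genotype_swap():
    expr = _expr_two_genotypes(80, 20, 60, 90)
    swapped = _expr_two_genotypes(60, 90, 80, 20)
    a = stability_change(expr, ("DSG", "PS"))["delta"]
    b = stability_change(swapped, ("DSG", "PS"))["delta"]
    np.testing.assert_allclose(a.to_numpy(), -b.to_numpy(), atol=1e-12)


def test_stability_groups_label_gene_sets():
    expr = _expr_two_genotypes(80, 20, 80, 80)
    table = stability_change(expr, ("DSG", "PS"), groups={"focal": {"g0"}})
    assert table.loc["g0", "group"] == "focal"
    assert table.loc["g1", "group"] == "other"


def test_ecdf_definition_and_properties():
    xs, fr = ecdf([1, 2, 3])
    assert fr[np.searchsorted(xs, 2)] == pytest.approx(2 / 3)
    assert fr[-1] == 1.0
    xs2, fr2 = ecdf([1.0, 2.0, 2.0, 3.0])
    assert list(xs2) == [1.0, 2.0, 3.0]
    assert fr2[1] == pytest.approx(0.75)  # duplicated value: one double step
    assert (np.diff(fr2) > 0).all()
    with pytest.raises(ValidationError):
        ecdf([])


def test_mann_whitney_null_identity_and_small_example():
    res = mann_whitney([1, 2], [1, 2])
    assert res.statistic == pytest.approx(2.0)  # n1*n2/2
    assert res.p_value == 1.0 and res.method == "exact"
    res2 = mann_whitney([1, 2], [3, 4])
    assert res2.statistic == 0.0
    assert res2.p_value == pytest.approx(2 / 6)


def _enumeration_oracle(x, y, alternative):
    """Independent permutation enumeration with plain python loops."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_of(subset):
        rest = [pooled[i] for i in range(len(pooled)) if i not in set(subset)]
        u = 0.0
        for i in subset:
            for v in rest:
                if pooled[i] > v:
                    u += 1.0
                elif pooled[i] == v:
                    u += 0.5
        return u

    u_obs = u_of(range(n1))
    mu = n1 * len(y) / 2.0
    us = [u_of(s) for s in itertools.combinations(range(len(pooled)), n1)]
    eps = 1e-9
    if alternative == "two-sided":
        hits = sum(abs(u - mu) >= abs(u_obs - mu) - eps for u in us)
    elif alternative == "greater":
        hits = sum(u >= u_obs - eps for u in us)
    else:
        hits = sum(u <= u_obs + eps for u in us)
    return u_obs, hits / len(us)


def test_exact_mann_whitney_matches_enumeration_oracle():
    rng = np.random.default_rng(2)
    for n1 in range(1, 6):
        for n2 in range(1, 11 - n1):
            for _ in range(3):
                x = rng.integers(0, 4, n1).astype(float)
                y = rng.integers(0, 4, n2).astype(float)
                for alternative in ("two-sided", "greater", "less"):
                    got = mann_whitney(x, y, alternative=alternative)
                    u_ref, p_ref = _enumeration_oracle(x, y, alternative)
                    assert got.method == "exact"
                    assert got.statistic == pytest.approx(u_ref)
                    assert got.p_value == pytest.approx(p_ref)


def test_mann_whitney_normal_mode_matches_scipy_without_ties():
    from scipy import stats

    rng = np.random.default_rng(3)
    x = rng.normal(0.4, 1, 30)
    y = rng.normal(0.0, 1, 40)
    got = mann_whitney(x, y)
    ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert got.method == "normal"
    assert got.statistic == pytest.approx(ref.statistic)
    assert got.p_value == pytest.approx(ref.pvalue, rel=1e-6)


def test_mann_whitney_rejects_empty_samples():
    with pytest.raises(ValidationError):
        mann_whitney([], [1.0])


def test_fold_increase_examples():
    assert round(fold_increase(286, 3365), 1) == 10.8
    assert fold_increase(100, 100) == 0.0
    assert fold_increase(100, 250) == 1.5
    assert math.isnan(fold_increase(0, 10))
    # exact for rational relative increases
    assert fold_increase(400, 400 * 7 // 4) == pytest.approx(3 / 4)


def test_report_round_trips_and_is_consistent(tmp_path, small_config):
    from phaseclear import run_synthetic

    result, truth = run_synthetic(small_config)
    path = tmp_path / "report.json"
    result.summary.to_json(path)
    back = SummaryReport.from_json(path)
    assert back == result.summary
    data = back.data
    assert data["decay"]["delayed"] == len(result.classification.delayed)
    assert data["decay"]["degraded"] == len(result.classification.degraded)
    assert data["rip"]["n_final_targets"] == len(result.rip_call.final_targets)
    assert data["de"]["n_down"] == len(result.down_set)
    ov = data["overlaps"]["down"]
    assert ov["percent"] == round(100 * ov["numerator"] / ov["denominator"], 2)
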