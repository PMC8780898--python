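"""Four-criteria decay classification: set algebra, boundaries, invariants."""

import numpy as np
import pandas as pd
import pytest

from phaseclear import (
    classify,
    degraded_m6a_targets,
    delayed_decay_set,
    ko_fold_change,
    overlap_fraction,
)
from phaseclear.errors import ValidationError

from conftest import make_count_matrix


def test_degraded_intersection_examples():
    assert degraded_m6a_targets({"a", "b", "c"}, {"b", "c", "d"}, {"c", "d"}) == {"c"}
    assert degraded_m6a_targets({"a", "b"}, set(), {"a"}) == frozenset()
    perms = [
        degraded_m6a_targets(x, y, z)
        for x, y, z in [
            ({"a", "b", "c"}, {"b", "c"}, {"c"}),
            ({"b", "c"}, {"a", "b", "c"}, {"c"}),
        ]
    ]
    assert perms[0] == perms[1] == {"c"}


def test_universe_mismatch_is_an_error():
    universe = pd.Index(["a", "b"])
    with pytest.raises(ValidationError, match="universe"):
        degraded_m6a_targets({"a", "zzz"}, {"a"}, {"a"}, universe=universe)


def _expr_for_fc(mean_dsg, mean_ps):
    # one gene, knockout libraries only; counts scaled so the FPKM at the
    # two stages equals the requested means exactly (single-gene FPKM is
    # fixed by mass conservation, so use two genes and read gene 0)
    from phaseclear import compute_fpkm

    lib = 1_000_000

    def col(fpkm_value):
        c0 = int(round(fpkm_value * lib * 1000 / 1e9))
        return [c0, lib - c0]

    cm = make_count_matrix(
        {
            "k_d1": col(mean_dsg),
            "k_d2": col(mean_dsg),
            "k_p1": col(mean_ps),
            "k_p2": col(mean_ps),
        },
        sample_meta={
            "k_d1": ("vKO", "DSG", 1, "rna"),
            "k_d2": ("vKO", "DSG", 2, "rna"),
            "k_p1": ("vKO", "PS", 1, "rna"),
            "k_p2": ("vKO", "PS", 2, "rna"),
        },
        lengths=[1000, 1000],
    )
    return compute_fpkm(cm)


def test_ko_fold_change_plugin_arithmetic():
    expr = _expr_for_fc(5.0, 10.0)
    fc = ko_fold_change(expr, ("DSG", "PS"))
    assert fc["g0"] == pytest.approx(10.1 / 5.1, rel=1e-6)
    identical = ko_fold_change(_expr_for_fc(4.0, 4.0), ("DSG", "PS"))
    assert identical["g0"] == pytest.approx(1.0, rel=1e-6)
    # both stage means zero -> pseudocount ratio 1
    zero = ko_fold_change(_expr_for_fc(0.0, 0.0), ("DSG", "PS"))
    assert zero["g0"] == pytest.approx(1.0)


def test_ko_fold_change_missing_stage_errors(small_expr):
    with pytest.raises(ValidationError, match="XX"):
        ko_fold_change(small_expr, ("DSG", "XX"))


def test_delayed_set_threshold_is_strict():
    fc = pd.Series({"g1": 1.3, "g2": 1.1, "g3": 1.2})
    assert delayed_decay_set({"g1", "g2"}, fc) == {"g1"}
    assert delayed_decay_set({"g3"}, fc) == frozenset()
    assert delayed_decay_set({"g1", "g2", "g3"}, fc, threshold=1.0) == {"g1", "g2", "g3"}
    with pytest.raises(ValidationError, match="g9"):
        delayed_decay_set({"g9"}, fc)


def test_raising_threshold_never_enlarges_delayed_set():
    rng = np.random.default_rng(0)
    fc = pd.Series(rng.uniform(0.5, 2.5, 100), index=[f"g{i}" for i in range(100)])
    degraded = set(fc.index[:60])
    previous = None
    for thr in [1.0, 1.1, 1.2, 1.5, 2.0]:
        current = delayed_decay_set(degraded, fc, thr)
        if previous is not None:
            assert current <= previous
        previous = current


def test_overlap_fraction_printed_examples():
    deg = [f"d{i}" for i in range(955)]
    both = set(deg[:79])
    assert overlap_fraction(deg, both, both) == (79, 955, 8.27)
    deg_up = [f"u{i}" for i in range(804)]
    both_up = set(deg_up[:36])
    assert overlap_fraction(deg_up, both_up, both_up) == (36, 804, 4.48)
    assert overlap_fraction(deg, set(), set()) == (0, 955, 0.0)
    assert overlap_fraction([], {"a"}, {"a"}) == (0, 0, 0.0)


def test_classifier_matches_bruteforce_predicates():
    rng = np.random.default_rng(1)
    universe = pd.Index([f"g{i}" for i in range(50)])
    down = set(rng.choice(universe, 20, replace=False))
    m6a = set(rng.choice(universe, 25, replace=False))
    targets = set(rng.choice(universe, 15, replace=False))
    fc = pd.Series(rng.uniform(0.5, 2.0, 50), index=universe)
    result = classify(universe, down_set=down, m6a_prev=m6a, targets=targets, ko_fc=fc)
    for g in universe:
        c1, c2, c3, c4 = g in down, g in m6a, g in targets, fc[g] > 1.2
        assert (g in result.degraded) == (c1 and c2 and c3)
        assert (g in result.delayed) == (c1 and c2 and c3 and c4)
    assert result.delayed <= result.degraded <= frozenset(down)
    labels = result.table["label"]
    assert set(labels.unique()) <= {"none", "degraded_only", "delayed"}
    assert (labels == "delayed").sum() == len(result.delayed)


def test_enlarging_inputs_never_shrinks_degraded():
    universe = pd.Index([f"g{i}" for i in range(30)])
    fc = pd.Series(1.5, index=universe)
    small = classify(
        universe, down_set=set(universe[:10]), m6a_prev=set(universe[:8]),
        targets=set(universe[:6]), ko_fc=fc,
    )
    big = classify(
        universe, down_set=set(universe[:15]), m6a_prev=set(universe[:12]),
        targets=set(universe[:9]), ko_fc=fc,
    )
    assert small.degraded <= big.degraded
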