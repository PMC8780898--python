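"""Size factors, dispersion, NB Wald test, BH adjustment, DEG calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phaseclear.de import (
    DEThresholds,
    bh_adjust,
    call_degs,
    dispersion_mom,
    de_contrast,
    moderate_dispersion,
    nb_wald_test,
    normalized_counts,
    size_factors,
)
from phaseclear.errors import ValidationError

from conftest import make_count_matrix


# -- size factors -----------------------------------------------------------

def test_size_factors_identity_and_doubling():
    identical = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]})
    np.testing.assert_allclose(size_factors(identical), 1.0)
    doubled = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
    np.testing.assert_allclose(
        size_factors(doubled), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
    )


def test_size_factors_invariant_under_gene_permutation():
    rng = np.random.default_rng(1)
    counts = pd.DataFrame(rng.poisson(80, (60, 4)), columns=list("abcd"))
    counts += 1
    perm = counts.sample(frac=1, random_state=2)
    np.testing.assert_allclose(size_factors(counts), size_factors(perm))


def test_size_factors_recover_scalar_column_multiples():
    rng = np.random.default_rng(3)
    base = rng.poisson(200, 100) + 1
    scalars = np.array([0.5, 1.0, 2.0, 4.0])
    counts = pd.DataFrame(
        {f"s{i}": np.round(base * k).astype(int) for i, k in enumerate(scalars)}
    )
    sf = size_factors(counts).to_numpy()
    ratio = sf / scalars
    np.testing.assert_allclose(ratio, ratio[0], rtol=0.02)


def test_size_factors_match_pydeseq2_reference():
    pydeseq2 = pytest.importorskip("pydeseq2")
    from pydeseq2.dds import DeseqDataSet

    rng = np.random.default_rng(4)
    counts = pd.DataFrame(
        rng.poisson(rng.uniform(20, 300, 80)[:, None] * rng.uniform(0.5, 2, 6), (80, 6)),
        columns=[f"s{i}" for i in range(6)],
    )
    meta = pd.DataFrame({"condition": ["a"] * 3 + ["b"] * 3}, index=counts.columns)
    dds = DeseqDataSet(counts=counts.T, metadata=meta, design="~condition", quiet=True)
    dds.fit_size_factors()
    np.testing.assert_allclose(
        size_factors(counts).to_numpy(), dds.obs["size_factors"].to_numpy(), rtol=1e-6
    )


def test_size_factors_error_without_common_nonzero_gene():
    counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
    with pytest.raises(ValidationError, match="pseudo-reference"):
        size_factors(counts)


# -- dispersion -------------------------------------------------------------

def test_dispersion_moment_plugin_and_floor():
    # two groups of three samples each, constructed so the pooled
    # within-group variance is 600 at mean 100 -> alpha = 0.05
    a = 100 + np.array([-20, 0, 20]) * np.sqrt(600 / 400)
    counts = pd.DataFrame([np.r_[a, a]], index=["g0"], columns=list("abcdef"))
    groups = dict(zip("abcdef", "AAABBB"))
    alpha = dispersion_mom(counts, groups)
    assert alpha["g0"] == pytest.approx((600 - 100) / 100**2, rel=1e-9)
    # Poisson-like gene: variance approximately the mean -> floored
    poisson_like = pd.DataFrame([[99.0, 100.0, 101.0, 99.0, 100.0, 101.0]],
                                index=["g0"], columns=list("abcdef"))
    assert dispersion_mom(poisson_like, groups)["g0"] == pytest.approx(1e-8)
    # negative moment estimate clipped to the floor
    flat = pd.DataFrame([[100.0] * 6], index=["g0"], columns=list("abcdef"))
    assert dispersion_mom(flat, groups)["g0"] == pytest.approx(1e-8)


def test_moderated_dispersion_tracks_the_common_truth():
    rng = np.random.default_rng(5)
    n, alpha_true = 2000, 0.05
    mu = rng.lognormal(5, 1, n)
    draws = rng.gamma(1 / alpha_true, alpha_true, (n, 4)) * mu[:, None]
    counts = pd.DataFrame(rng.poisson(draws), columns=list("abcd")).astype(float)
    groups = dict(zip("abcd", "AABB"))
    alpha = moderate_dispersion(counts, groups)
    median = float(np.median(alpha))
    assert 0.03 < median < 0.08
    # moderation tightens the spread relative to the raw per-gene estimate
    raw = dispersion_mom(counts, groups)
    assert alpha.std() < raw.std() / 2


# -- Wald test --------------------------------------------------------------

def test_identical_groups_give_null_statistics():
    counts = pd.DataFrame(
        {"a1": [30, 0, 7], "a2": [60, 0, 9], "b1": [30, 0, 7], "b2": [60, 0, 9]}
    )
    sf = pd.Series(1.0, index=counts.columns)
    alpha = pd.Series(0.05, index=counts.index)
    res = nb_wald_test(counts, sf, ["a1", "a2"], ["b1", "b2"], alpha)
    assert res.loc[0, "log2fc"] == 0
    assert res.loc[0, "wald_stat"] == 0
    assert res.loc[0, "p_value"] == pytest.approx(1.0)
    # all-zero gene: flagged missing
    assert np.isnan(res.loc[1, "p_value"]) and np.isnan(res.loc[1, "padj"])
    assert res.loc[1, "log2fc"] == 0


def test_single_replicate_group_reports_fc_without_p():
    counts = pd.DataFrame({"a1": [10], "b1": [40], "b2": [40]})
    sf = pd.Series(1.0, index=counts.columns)
    res = nb_wald_test(counts, sf, ["a1"], ["b1", "b2"], pd.Series(0.05, index=counts.index))
    assert res.loc[0, "log2fc"] == pytest.approx(np.log2(40.5 / 10.5))
    assert np.isnan(res.loc[0, "p_value"])


def test_planted_fourfold_change_is_detected_with_high_power():
    # 200 replicate simulations of one gene, NB alpha=0.05, 5 vs 5 samples
    rng = np.random.default_rng(6)
    n_sim, alpha_true = 200, 0.05
    mu_a, mu_b = 100.0, 400.0
    draws_a = rng.poisson(rng.gamma(1 / alpha_true, alpha_true, (n_sim, 5)) * mu_a)
    draws_b = rng.poisson(rng.gamma(1 / alpha_true, alpha_true, (n_sim, 5)) * mu_b)
    counts = pd.DataFrame(
        np.hstack([draws_a, draws_b]), columns=[f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
    )
    sf = pd.Series(1.0, index=counts.columns)
    alpha = pd.Series(alpha_true, index=counts.index)
    res = nb_wald_test(counts, sf, [f"a{i}" for i in range(5)], [f"b{i}" for i in range(5)], alpha)
    hits = ((res["log2fc"] > 0) & (res["p_value"] < 0.05)).mean()
    assert hits >= 0.95


def test_swapping_groups_negates_fold_changes_and_swaps_calls(small_counts):
    res_ab = de_contrast(
        small_counts, factor="stage", level_a="DSG", level_b="PS",
        where={"genotype": "control", "assay": "rna"},
    )
    res_ba = de_contrast(
        small_counts, factor="stage", level_a="PS", level_b="DSG",
        where={"genotype": "control", "assay": "rna"},
    )
    np.testing.assert_allclose(
        res_ab["log2fc"].to_numpy(), -res_ba["log2fc"].to_numpy(), atol=1e-9
    )
    thr = DEThresholds()
    up_ab, down_ab = call_degs(res_ab, thr)
    up_ba, down_ba = call_degs(res_ba, thr)
    assert up_ab == down_ba and down_ab == up_ba


# -- BH ---------------------------------------------------------------------

def test_bh_worked_examples():
    np.testing.assert_allclose(
        bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )
    np.testing.assert_allclose(bh_adjust([0.01, 0.5]), [0.02, 0.5])
    np.testing.assert_allclose(bh_adjust([0.37]), [0.37])
    out = bh_adjust([0.01, np.nan, 0.5])
    np.testing.assert_allclose(out[[0, 2]], [0.02, 0.5])
    assert np.isnan(out[1])
    with pytest.raises(ValidationError):
        bh_adjust([0.5, 1.2])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=200))
def test_bh_matches_statsmodels_and_is_monotone(p):
    from statsmodels.stats.multitest import multipletests

    ours = bh_adjust(p).to_numpy()
    ref = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(ours, ref, rtol=1e-12, atol=1e-12)
    order = np.argsort(p, kind="stable")
    assert (np.diff(ours[order]) >= -1e-12).all()


# -- DEG calls --------------------------------------------------------------

def test_deg_call_boundaries_are_strict():
    res = pd.DataFrame(
        {
            "log2fc": [-0.7, 0.7, np.log2(1.5), -np.log2(1.5), 2.0],
            "padj": [0.04, 0.04, 0.01, 0.01, 0.05],
        },
        index=list("abcde"),
    )
    up, down = call_degs(res, DEThresholds())
    assert down == {"a"}  # FC about 1.62 down, significant
    assert up == {"b"}
    # c, d sit exactly at |log2fc| = log2(1.5); e exactly at padj = 0.05
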