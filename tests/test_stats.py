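import numpy as np
import pandas as pd
import pytest

import reference as ref
from mrtrust.stats import (
    DEMO_TERMS,
    group_compare,
    kendall_matrix,
    ols_fit,
    ordinal_fit,
    stepwise_aic,
    zero_investment_shares,
    zscore,
)


def test_zscore_basic():
    z = zscore([1.0, 2.0, 3.0])
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std(ddof=1) == pytest.approx(1.0)
    np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])
    # squaring happens after z-scoring
    np.testing.assert_allclose(zscore([1.0, 2.0, 3.0]) ** 2, z**2)
    with pytest.raises(ValueError):
        zscore([2.0, 2.0, 2.0])


def test_ols_matches_normal_equations():
    """Coefficients agree with the lstsq solution on random small designs."""
    rng = np.random.default_rng(0)
    for _ in range(5):
        n = 40
        df = pd.DataFrame(rng.standard_normal((n, 3)), columns=["x1", "x2", "x3"])
        df["y"] = rng.standard_normal(n)
        res = ols_fit(df, "y", ("x1", "x2", "x3"))
        X = np.column_stack([np.ones(n), df[["x1", "x2", "x3"]].to_numpy()])
        beta, *_ = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)
        got = [res.coefficients[t] for t in ("const", "x1", "x2", "x3")]
        np.testing.assert_allclose(got, beta, atol=1e-8)


def test_ols_exact_linear_data_has_adj_r2_one():
    df = pd.DataFrame({"x": np.arange(10.0)})
    df["y"] = 2 * df["x"] - 3
    assert ols_fit(df, "y", ("x",)).adj_r2 == pytest.approx(1.0)


def test_ols_independent_outcome_has_near_zero_adj_r2():
    rng = np.random.default_rng(1)
    df = pd.DataFrame({"x": rng.standard_normal(10000), "y": rng.standard_normal(10000)})
    assert abs(ols_fit(df, "y", ("x",)).adj_r2) < 0.01


def test_ols_drops_rank_deficient_terms():
    df = pd.DataFrame({"x": np.arange(10.0), "c": np.ones(10)})
    df["y"] = df["x"] + 1
    with pytest.warns(UserWarning):
        res = ols_fit(df, "y", ("x", "c"))
    assert res.dropped_terms == ("c",)


def test_ordinal_binary_slope_equals_log_odds_ratio():
    """With a binary outcome and a single binary predictor the
    proportional-odds slope is the 2x2 log odds ratio."""
    rows = []
    counts = {(0, 0): 40, (0, 1): 20, (1, 0): 15, (1, 1): 45}
    for (x, y), c in counts.items():
        rows += [{"x": x, "y": y}] * c
    df = pd.DataFrame(rows)
    res = ordinal_fit(df, "y", ("x",))
    lor = np.log(counts[(1, 1)] * counts[(0, 0)] / (counts[(1, 0)] * counts[(0, 1)]))
    assert res.coefficients["x"] == pytest.approx(lor, abs=1e-3)
    assert len(res.thresholds) == 1


def test_ordinal_zero_effect_slope_near_zero():
    rng = np.random.default_rng(2)
    df = pd.DataFrame({
        "x": rng.standard_normal(2000),
        "y": rng.integers(0, 3, size=2000),
    })
    res = ordinal_fit(df, "y", ("x",))
    assert abs(res.coefficients["x"]) < 0.1


def test_ordinal_positive_slope_shifts_mass_upward():
    rng = np.random.default_rng(3)
    x = rng.standard_normal(2000)
    latent = 1.5 * x + rng.logistic(size=2000)
    y = np.digitize(latent, [-1.0, 1.0])
    df = pd.DataFrame({"x": x, "y": y})
    res = ordinal_fit(df, "y", ("x",))
    assert res.coefficients["x"] > 1.0  # positive = toward higher categories
    assert list(res.thresholds) == sorted(res.thresholds)


def test_stepwise_keeps_strong_terms_and_drops_noise():
    rng = np.random.default_rng(4)
    n = 600
    df = pd.DataFrame(rng.standard_normal((n, 4)), columns=["s", "n1", "n2", "n3"])
    df["y"] = 3.0 * df["s"] + rng.standard_normal(n)
    res = stepwise_aic(df, "y", ("s", "n1", "n2", "n3"), ols_fit)
    assert "s" in res.terms
    assert set(res.terms) <= {"s", "n1", "n2", "n3"}
    # AIC of selection never above the full model's
    full = ols_fit(df, "y", ("s", "n1", "n2", "n3"))
    assert res.aic <= full.aic + 1e-9


def test_stepwise_pure_noise_selects_intercept_only_mostly():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        df = pd.DataFrame(rng.standard_normal((300, 3)), columns=["a", "b", "c"])
        df["y"] = rng.standard_normal(300)
        res = stepwise_aic(df, "y", ("a", "b", "c"), ols_fit)
        if not res.terms:
            hits += 1
    assert hits >= 6


def test_kendall_matrix_matches_bruteforce():
    rng = np.random.default_rng(5)
    df = pd.DataFrame({
        "a": rng.integers(0, 4, size=40).astype(float),
        "b": rng.integers(0, 4, size=40).astype(float),
        "c": rng.standard_normal(40),
    })
    tab = kendall_matrix(df, ["a", "b", "c"])
    for x in ("a", "b", "c"):
        assert tab.tau.loc[x, x] == 1.0
        for y in ("a", "b", "c"):
            if x == y:
                continue
            brute = ref.kendall_tau_b_bruteforce(df[x].tolist(), df[y].tolist())
            assert tab.tau.loc[x, y] == pytest.approx(brute, abs=1e-12)
            assert tab.tau.loc[x, y] == tab.tau.loc[y, x]


def test_kendall_perfect_orders():
    df = pd.DataFrame({"u": [1.0, 2, 3, 4, 5], "v": [2.0, 4, 6, 8, 10],
                       "w": [5.0, 4, 3, 2, 1]})
    tab = kendall_matrix(df, ["u", "v", "w"])
    assert tab.tau.loc["u", "v"] == pytest.approx(1.0)
    assert tab.tau.loc["u", "w"] == pytest.approx(-1.0)


def test_kendall_tied_example_bruteforce():
    x = [1.0, 2.0, 2.0, 3.0, 4.0]
    y = [1.0, 3.0, 2.0, 2.0, 4.0]
    df = pd.DataFrame({"x": x, "y": y})
    tab = kendall_matrix(df, ["x", "y"])
    assert tab.tau.loc["x", "y"] == pytest.approx(
        ref.kendall_tau_b_bruteforce(x, y), abs=1e-12
    )


def test_group_compare_identical_groups():
    v = np.concatenate([np.arange(10.0), np.arange(10.0)])
    g = [0] * 10 + [1] * 10
    res = group_compare(v, g)
    assert res.cohens_d == pytest.approx(0.0)
    assert res.ci_low < 0 < res.ci_high


def test_group_compare_unit_shift_has_d_about_one():
    rng = np.random.default_rng(6)
    v = np.concatenate([rng.normal(1.0, 1.0, 10000), rng.normal(0.0, 1.0, 10000)])
    g = [0] * 10000 + [1] * 10000
    res = group_compare(v, g)
    assert res.cohens_d == pytest.approx(1.0, abs=0.05)
    assert res.mean_difference == pytest.approx(1.0, abs=0.05)


def test_group_compare_scale_equivariance():
    rng = np.random.default_rng(7)
    v = rng.standard_normal(100) + np.array([0.0] * 50 + [1.0] * 50)
    g = [0] * 50 + [1] * 50
    r1 = group_compare(v, g)
    r2 = group_compare(2 * v, g)
    assert r2.mean_difference == pytest.approx(2 * r1.mean_difference)
    assert r2.cohens_d == pytest.approx(r1.cohens_d)


def test_zero_investment_share_arithmetic():
    male, female = zero_investment_shares(159, 88)
    assert male == pytest.approx(64.4, abs=0.05)
    assert female == pytest.approx(35.6, abs=0.05)
    nan_m, nan_f = zero_investment_shares(0, 0)
    assert np.isnan(nan_m) and np.isnan(nan_f)
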