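"""Screening, count GLMs, AICc selection, averaging, partitioning."""

import numpy as np
import pandas as pd
import pytest
from _oracles import _ols_r2, shapley_partition_r2

from funcniche.habitat import (aicc, akaike_weights, all_subsets,
                               correlation_screen, fit_glm,
                               hierarchical_partition, model_average,
                               normality_screen)
from funcniche.synthetic import SimulationConfig, generate_counts, generate_environments


@pytest.fixture(scope="module")
def big_env():
    return generate_environments(SimulationConfig(seed=21), n_transects=2000)


# ----------------------------------------------------------- screening

def test_normality_screen_flags(rng):
    df = pd.DataFrame({
        "gauss": rng.standard_normal(100),
        "lognorm": np.exp(rng.standard_normal(100) * 1.2),
        "const": np.ones(100),
    })
    res = normality_screen(df)
    assert res.loc["gauss", "normal"] == True  # noqa: E712
    assert res.loc["lognorm", "p"] < 0.05
    assert np.isnan(res.loc["const", "W"])
    with pytest.raises(ValueError, match="at least 3"):
        normality_screen(df.iloc[:2])


def test_correlation_screen_drops_duplicate_column(rng):
    x = rng.standard_normal(50)
    df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.standard_normal(50)})
    res = correlation_screen(df, keep_rules={("a", "b"): "a"})
    assert res.kept == ["a", "c"]
    assert res.dropped == ["b"]


def test_correlation_screen_keeps_independent_variables(rng):
    df = pd.DataFrame(rng.standard_normal((200, 5)),
                      columns=list("abcde"))
    res = correlation_screen(df, keep_rules={})
    assert res.dropped == []


def test_correlation_screen_default_rules_on_synthetic_env(big_env):
    res = correlation_screen(big_env)
    assert "SGT" in res.dropped and "ST" in res.kept
    assert "BSC" in res.dropped and "CGC" in res.kept
    assert res.method.loc["SGT", "ST"] in ("pearson", "spearman")
    with pytest.raises(ValueError, match="absent"):
        correlation_screen(big_env, keep_rules={("SGT", "XX"): "SGT"})


# ----------------------------------------------------------------- GLM

def test_intercept_only_glm_closed_form():
    counts = np.full(20, 7.0)
    fit = fit_glm(counts, pd.DataFrame(index=range(20)))
    assert fit.params["const"] == pytest.approx(np.log(7.0), abs=1e-8)


def test_glm_sample_size_guard(rng):
    X = pd.DataFrame(rng.standard_normal((4, 3)), columns=list("abc"))
    with pytest.raises(ValueError, match="n >= k"):
        fit_glm(rng.poisson(3, 4).astype(float), X)


def test_poisson_wald_interval_coverage(rng):
    """95% Wald intervals cover the true coefficient ~95% of the time."""
    hits = 0
    n_rep = 200
    for i in range(n_rep):
        x = rng.standard_normal(300)
        mu = np.exp(1.0 + 0.5 * (x - x.mean()) / x.std(ddof=1))
        y = rng.poisson(mu)
        fit = fit_glm(y, pd.DataFrame({"x": x}))
        hits += abs(fit.params["x"] - 0.5) <= 1.96 * fit.se["x"]
    assert hits / n_rep == pytest.approx(0.95, abs=0.05)


# ---------------------------------------------------------------- AICc

def test_aicc_arithmetic_and_limits():
    assert aicc(-10.0, 3, 11) == pytest.approx(20 + 6 + 24 / 7, abs=1e-10)
    assert aicc(-10.0, 0, 11) == pytest.approx(20.0)
    assert aicc(-10.0, 3, 10**9) == pytest.approx(-2 * -10.0 + 6, abs=1e-3)
    with pytest.raises(ValueError, match="undefined"):
        aicc(-10.0, 10, 11)


def test_akaike_weights_proportionality():
    w = akaike_weights(np.array([0.0, 2.0, 4.0]))
    expected = np.array([1.0, np.exp(-1.0), np.exp(-2.0)])
    expected /= expected.sum()
    assert np.allclose(w, expected, atol=1e-12)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)
    # invariant to a constant shift of all AICc values
    assert np.allclose(akaike_weights(np.array([10.0, 12.0, 14.0])), w, atol=1e-12)


# ------------------------------------------------------- all-subsets

def test_all_subsets_enumeration_and_weights(big_env, rng):
    env = big_env.iloc[:60][["AT", "AH", "slope"]]
    counts = generate_counts(big_env.iloc[:60], {"intercept": np.log(6.0)}, seed=1)
    mt = all_subsets(counts, env)
    assert len(mt.table) == 8  # 2^3 subsets
    ok = mt.table[mt.table["status"] == "ok"]
    assert ok["weight"].sum() == pytest.approx(1.0, abs=1e-8)
    assert ok["delta"].iloc[0] == 0.0


def test_all_subsets_strong_predictor_and_best_model_rule():
    """A strong effect always tops the ranking; a single best model is
    declared exactly when the runner-up trails by more than 2 AICc."""
    for seed in range(8):
        env = generate_environments(SimulationConfig(seed=seed), n_transects=15)
        counts = generate_counts(env, {"intercept": np.log(10.0), "ST": 1.2},
                                 seed=seed)
        mt = all_subsets(counts, env[["AT", "ST", "slope"]])
        ok = mt.table[mt.table["status"] == "ok"].reset_index(drop=True)
        assert "ST" in ok.loc[0, "subset"]
        runner_delta = ok.loc[1, "delta"]
        assert mt.ambiguous == (runner_delta <= 2.0)
        if mt.best is not None:
            assert not mt.ambiguous and "ST" in mt.best


def test_all_subsets_noise_keeps_null_model_close(big_env):
    env = big_env.iloc[:80][["AT", "AH"]]
    counts = generate_counts(big_env.iloc[:80], {"intercept": np.log(5.0)}, seed=9)
    mt = all_subsets(counts, env)
    ok = mt.table[mt.table["status"] == "ok"].reset_index(drop=True)
    null_delta = ok.loc[ok["subset"].map(len) == 0, "delta"].iloc[0]
    assert null_delta < 6.0  # intercept-only stays competitive on pure noise


# ------------------------------------------------------ model averaging

def test_model_average_single_model_scope(big_env):
    env = big_env.iloc[:100][["ST"]]
    counts = generate_counts(big_env.iloc[:100],
                             {"intercept": np.log(10.0), "ST": 1.2}, seed=4)
    mt = all_subsets(counts, env)
    # with this effect size the ST model carries essentially all weight
    avg_d2 = model_average(mt, scope="delta2")
    top_fit = mt.fits[tuple(mt.table.loc[0, "subset"])]
    assert avg_d2.loc["ST", "coef"] == pytest.approx(top_fit.params["ST"], rel=1e-6)
    assert avg_d2.loc["ST", "se"] == pytest.approx(top_fit.se["ST"], rel=1e-6)


def test_model_average_scopes_and_errors(big_env):
    env = big_env.iloc[:60][["AT", "AH"]]
    counts = generate_counts(big_env.iloc[:60], {"intercept": np.log(5.0)}, seed=6)
    mt = all_subsets(counts, env)
    for scope in ("all", "delta2", "cum95"):
        avg = model_average(mt, scope=scope)
        assert {"coef", "se", "z", "p", "sel_prob"} <= set(avg.columns)
    with pytest.raises(ValueError, match="scope"):
        model_average(mt, scope="nope")


def test_full_average_shrinks_noise_coefficients(big_env):
    env = big_env.iloc[:100][["ST", "AT"]]
    counts = generate_counts(big_env.iloc[:100],
                             {"intercept": np.log(10.0), "ST": 1.0}, seed=8)
    mt = all_subsets(counts, env)
    avg = model_average(mt, scope="all")
    st_single = mt.fits[("ST",)].params["ST"]
    assert abs(avg.loc["AT", "coef"]) < abs(avg.loc["ST", "coef"])
    assert avg.loc["ST", "coef"] == pytest.approx(st_single, rel=0.1)


# --------------------------------------------- hierarchical partitioning

def test_partition_single_predictor_is_its_own_gof(rng):
    x = rng.standard_normal(80)
    y = 2.0 + 1.5 * x + rng.standard_normal(80)
    res = hierarchical_partition(y, pd.DataFrame({"x": x}), family="gaussian")
    assert res.table.loc["x", "I"] == pytest.approx(res.full_gof, abs=1e-10)
    assert res.table.loc["x", "J"] == pytest.approx(0.0, abs=1e-10)


def test_partition_orthogonal_predictors_have_zero_joint(rng):
    n = 64
    a = np.tile([1.0, -1.0], n // 2)
    b = np.repeat([1.0, -1.0], n // 2)
    assert abs(a @ b) < 1e-12
    y = 0.8 * a + 0.4 * b + rng.standard_normal(n) * 0.5
    X = pd.DataFrame({"a": a, "b": b})
    res = hierarchical_partition(y, X, family="gaussian")
    for v in ("a", "b"):
        marginal = _ols_r2(y, X[[v]].to_numpy())
        assert res.table.loc[v, "I"] == pytest.approx(marginal, abs=1e-8)
        assert res.table.loc[v, "J"] == pytest.approx(0.0, abs=1e-8)
    # with zero joint contributions the I+J total equals the full-model fit
    assert (res.table["I"] + res.table["J"]).sum() == pytest.approx(
        res.full_gof, abs=1e-8)


def test_partition_matches_bruteforce_shapley(rng):
    n = 60
    L = np.array([[1.0, 0.0, 0.0], [0.6, 0.8, 0.0], [0.3, 0.4, 0.87]])
    X = rng.standard_normal((n, 3)) @ L.T  # correlated design
    y = 1.0 + X @ np.array([0.8, -0.5, 0.3]) + rng.standard_normal(n)
    df = pd.DataFrame(X, columns=["a", "b", "c"])
    res = hierarchical_partition(y, df, family="gaussian")
    oracle = shapley_partition_r2(y, X)
    assert np.allclose(res.table["I"].to_numpy(), oracle, atol=1e-8)
    assert res.table["I"].sum() == pytest.approx(res.full_gof, abs=1e-8)


def test_partition_poisson_deviance_explained(big_env):
    env = big_env.iloc[:80][["ST", "AT", "slope"]]
    counts = generate_counts(big_env.iloc[:80],
                             {"intercept": np.log(8.0), "ST": 0.7}, seed=12)
    res = hierarchical_partition(counts, env, family="poisson")
    assert res.table["I"].sum() == pytest.approx(res.full_gof, abs=1e-8)
    assert res.table.loc["ST", "I"] == res.table["I"].max()
    assert res.table["I_pct"].sum() == pytest.approx(100.0, abs=1e-6)


def test_partition_survives_boundary_fits():
    """Near-saturated Poisson hierarchies with zero counts (rates driven
    to the boundary) still yield a finite, complete partition."""
    env = generate_environments(SimulationConfig(seed=3))
    counts = np.array([0, 5, 21, 1, 3, 4, 0, 0, 1, 4, 1])
    res = hierarchical_partition(
        counts, env[["AT", "AH", "SH", "slope", "Illu", "RC", "CGC"]])
    assert np.all(np.isfinite(res.table.to_numpy()))
    assert res.table["I"].sum() == pytest.approx(res.full_gof, abs=1e-6)
    assert 0.0 <= res.full_gof <= 1.0 + 1e-9
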