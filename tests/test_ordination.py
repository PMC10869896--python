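"""DCA gradient gate and redundancy analysis."""

import os
import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest

from funcniche.ordination import (cca, dca_gradient_length, forward_select, rda,
                                  rda_permutation_test)


def coenocline(rng, span, n_sites=60, n_species=25, tol=1.0):
    """Gaussian species turnover along a gradient of the given SD span."""
    grad = np.sort(rng.uniform(0, span, n_sites))
    opt = rng.uniform(0, span, n_species)
    mu = 30 * np.exp(-((grad[:, None] - opt[None, :]) ** 2) / (2 * tol**2))
    X = rng.poisson(mu)
    X = X[:, X.sum(axis=0) > 0]
    return X[X.sum(axis=1) > 0]


# ------------------------------------------------------------------ DCA

def test_identical_rows_have_zero_gradient():
    X = np.tile([3.0, 1.0, 2.0, 4.0], (6, 1))
    res = dca_gradient_length(X)
    assert res.axis1_gradient_length == 0.0
    assert res.recommendation == "rda"


def test_long_coenocline_recommends_cca(rng):
    X = coenocline(rng, span=8.0)
    res = dca_gradient_length(X)
    assert res.axis1_gradient_length > 3.0
    assert res.recommendation == "cca"


def test_trait_matrix_gradient_is_short(std_traits):
    res = dca_gradient_length(std_traits.data)
    assert res.axis1_gradient_length < 3.0
    assert res.recommendation == "rda"


def test_dca_degenerate_inputs():
    with pytest.raises(ValueError, match="2-D matrix"):
        dca_gradient_length(np.ones(5))
    with pytest.raises(ValueError, match="all-zero"):
        dca_gradient_length(np.array([[0.0, 0.0], [1.0, 2.0], [2.0, 1.0]]))


@pytest.mark.parametrize("span, n_seed", [(1.0, 1), (8.0, 2)])
def test_gate_agrees_with_decorana(span, n_seed):
    """The RDA/CCA recommendation matches vegan's decorana axis length."""
    rng = np.random.default_rng(n_seed)
    X = coenocline(rng, span=span)
    res = dca_gradient_length(X)
    with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as fh:
        pd.DataFrame(X).to_csv(fh.name, index=False)
        path = fh.name
    try:
        out = subprocess.run(
            ["Rscript", "-e",
             f'suppressMessages(library(vegan)); '
             f'm <- as.matrix(read.csv("{path}")); '
             f's <- scores(decorana(m), display="sites")[, 1]; '
             f'cat(max(s) - min(s))'],
            capture_output=True, text=True, timeout=120, check=True)
        ref_len = float(out.stdout.strip().split()[-1])
    finally:
        os.unlink(path)
    assert (res.axis1_gradient_length < 3.0) == (ref_len < 3.0)
    if ref_len < 5.0:  # segment rescaling diverges only on very long gradients
        assert res.axis1_gradient_length == pytest.approx(ref_len, rel=0.25)


def test_cca_is_explicitly_unavailable():
    with pytest.raises(NotImplementedError):
        cca()


# ------------------------------------------------------------------ RDA

def test_rda_variance_decomposition(std_traits, transects, individuals):
    env = individuals[["id", "transect"]].merge(
        transects, on="transect").set_index("id")
    env = env.loc[std_traits.ids, ["ST", "AH", "slope", "Illu"]]
    env = (env - env.mean()) / env.std(ddof=1)
    res = rda(std_traits.data, env)
    Y = std_traits.data - std_traits.data.mean()
    total = float((Y**2).sum().sum() / (len(Y) - 1))
    assert res.total_variance == pytest.approx(total, abs=1e-8)
    assert res.constrained_variance <= total + 1e-8
    assert np.all(res.pct_of_total >= -1e-12)
    assert res.pct_of_total.sum() == pytest.approx(
        100 * res.constrained_variance / total, abs=1e-8)


def test_rda_on_own_pcs_reproduces_their_variance(std_traits, space):
    """Constraining traits by their own PC scores is a self-regression:
    the canonical variance equals the variance of those PCs."""
    env = space.coordinates.iloc[:, :2]
    res = rda(std_traits.data, env)
    expected = env.var(ddof=1).to_numpy()
    assert np.allclose(np.sort(res.canonical_eigenvalues)[::-1],
                       np.sort(expected)[::-1], atol=1e-8)


def test_rda_full_basis_reproduces_pca(std_traits):
    """Using the traits themselves as constraints leaves nothing
    unexplained, so the canonical spectrum is the PCA spectrum."""
    Y = std_traits.data
    res = rda(Y, Y.copy())
    cov_eig = np.sort(np.linalg.eigvalsh(np.cov(Y.to_numpy(), rowvar=False)))[::-1]
    assert np.allclose(res.canonical_eigenvalues, cov_eig[: len(res.canonical_eigenvalues)],
                       atol=1e-8)
    assert res.constrained_variance == pytest.approx(res.total_variance, abs=1e-8)


def test_rda_matches_reference_implementation(rng):
    from skbio.stats.ordination import rda as skbio_rda

    Y = pd.DataFrame(rng.standard_normal((40, 5)))
    X = pd.DataFrame(rng.standard_normal((40, 3)), columns=list("abc"))
    Y.index = X.index = [f"s{i}" for i in range(40)]
    res = rda(Y, X)
    ref = skbio_rda(Y, X, scale_Y=False)
    # skbio reports the singular values of Y_hat; convert to variances
    n_can = len(res.canonical_eigenvalues)
    ref_eig = ref.eigvals.to_numpy()[:n_can] ** 2 / (len(Y) - 1)
    assert np.allclose(res.canonical_eigenvalues, ref_eig, atol=1e-8)


def test_rda_directional_effect_aligns_arrows(rng):
    n = 120
    drive = rng.standard_normal(n)
    Y = pd.DataFrame({
        "t1": drive + 0.2 * rng.standard_normal(n),
        "t2": rng.standard_normal(n),
        "t3": rng.standard_normal(n),
    })
    X = pd.DataFrame({"e1": drive + 0.1 * rng.standard_normal(n),
                      "e2": rng.standard_normal(n)})
    res = rda(Y, X)
    e1 = res.env_scores.loc["e1"].to_numpy()
    t1 = res.trait_scores.loc["t1"].to_numpy()
    cosine = e1 @ t1 / (np.linalg.norm(e1) * np.linalg.norm(t1))
    assert cosine > 0.9


def test_rda_rank_deficiency_names_columns(rng):
    X = pd.DataFrame(rng.standard_normal((30, 2)), columns=["a", "b"])
    X["c"] = X["a"] + X["b"]
    Y = pd.DataFrame(rng.standard_normal((30, 4)))
    with pytest.raises(ValueError, match="rank-deficient"):
        rda(Y, X)


def test_rda_permutation_test_behaviour(rng):
    n = 80
    drive = rng.standard_normal(n)
    Y = pd.DataFrame({"t1": drive, "t2": drive * 0.5 + rng.standard_normal(n)})
    X = pd.DataFrame({"e": drive + 0.1 * rng.standard_normal(n)})
    strong = rda_permutation_test(Y, X, n_perm=999, seed=1)
    assert strong["p"] == pytest.approx(1 / 1000)  # +1 convention floor
    again = rda_permutation_test(Y, X, n_perm=999, seed=1)
    assert again["p"] == strong["p"] and again["F"] == strong["F"]
    with pytest.raises(ValueError, match="n_perm"):
        rda_permutation_test(Y, X, n_perm=0)


def test_forward_select_recovers_driving_variable(rng):
    n = 100
    drive = rng.standard_normal(n)
    Y = pd.DataFrame({"t1": drive + 0.3 * rng.standard_normal(n),
                      "t2": rng.standard_normal(n)})
    X = pd.DataFrame({"sig": drive + 0.2 * rng.standard_normal(n),
                      "noise1": rng.standard_normal(n),
                      "noise2": rng.standard_normal(n)})
    selected = forward_select(Y, X, n_perm=199, seed=0)
    assert "sig" in selected
    assert len(selected) <= 2
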