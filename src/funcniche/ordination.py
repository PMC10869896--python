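"""Constrained ordination of traits on microhabitat: DCA gate, then RDA.

The gradient length of the first detrended-correspondence-analysis axis
decides between a linear-response model (RDA, gradient < 3 SD) and a
unimodal one (CCA, gradient >= 3 SD).  Axis 1 needs no detrending
(detrending removes axis-1 trends from *higher* axes), so the gate runs
correspondence analysis by reciprocal averaging and rescales axis-1 site
scores into species-turnover SD units via the mean species tolerance
(Hill's sigma units).

RDA itself is the PCA of the fitted values from a multivariate linear
regression of the (standardized) trait matrix on the environment matrix;
its significance is assessed with a permutation test on the pseudo-F of
constrained vs residual variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla

__all__ = [
    "DCAResult",
    "RDAResult",
    "cca",
    "dca_gradient_length",
    "forward_select",
    "rda",
    "rda_permutation_test",
]


# ----------------------------------------------------------------- DCA gate

@dataclass
class DCAResult:
    axis1_gradient_length: float
    n_segments: int
    recommendation: str  # "rda" if gradient < 3 SD else "cca"


def dca_gradient_length(matrix: pd.DataFrame | np.ndarray,
                        n_segments: int = 26) -> DCAResult:
    """Axis-1 gradient length in SD units and the RDA/CCA recommendation.

    Columns with negative entries are min-shifted to nonnegative first
    (correspondence analysis requires nonnegative abundances; trait
    matrices are shifted, not truncated).  Rows or columns that are
    entirely zero after the shift make the matrix degenerate and raise.

    The length is the range of axis-1 site scores divided by the
    abundance-weighted mean within-species dispersion (tolerance) of site
    scores, i.e. the number of species-turnover standard deviations the
    first gradient spans.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("DCA needs a 2-D matrix with >= 2 rows and columns")
    X = X - np.minimum(X.min(axis=0), 0.0)  # per-column min-shift
    if np.any(X.sum(axis=1) <= 0) or np.any(X.sum(axis=0) <= 0):
        raise ValueError("degenerate matrix: all-zero row or column after shift")

    total = X.sum()
    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    if sv[0] < 1e-12:
        # identical row profiles: no gradient at all
        return DCAResult(0.0, n_segments, "rda")

    # axis-1 site scores with unit weighted variance
    site = U[:, 0] / np.sqrt(r)
    site = site - np.sum(r * site)
    site = site / np.sqrt(np.sum(r * site**2))

    # deshrunken species scores (reciprocal-averaging step expanded by
    # 1/eigenvalue): near-linear data spreads every species across every
    # site, inflating the within-site dispersion of species scores and
    # thus shortening the gradient in SD units
    lam = sv[0] ** 2
    species = (P.T @ site) / c / lam
    row_profiles = P / r[:, None]
    site_mean = row_profiles @ species
    disp2 = np.maximum(row_profiles @ species**2 - site_mean**2, 0.0)
    # Hill's sd unit: rescale the axis so the abundance-weighted average
    # within-site dispersion of species scores equals 1
    s_bar = float(np.sqrt(np.sum(r * disp2)))
    length = float(np.ptp(site) / s_bar) if s_bar > 0 else 0.0
    return DCAResult(length, n_segments, "rda" if length < 3.0 else "cca")


def cca(*args, **kwargs):
    """Canonical correspondence analysis - not implemented.

    The DCA gate recommends RDA for short gradients; CCA is only needed
    for gradients >= 3 SD, which this package does not cover.
    """
    raise NotImplementedError("CCA is not implemented; the DCA gate selects RDA "
                              "for gradients < 3 SD")


# --------------------------------------------------------------------- RDA

@dataclass
class RDAResult:
    """Redundancy analysis of traits constrained by environment.

    ``canonical_eigenvalues`` are variances (ddof = 1) of the fitted-value
    principal axes; ``pct_of_total`` scales them by the total trait
    variance.  Scores follow a correlation ("type 2") triplot reading:
    ``env_scores`` and ``trait_scores`` are correlations of each variable
    with the site scores, so the cosine between an environment arrow and
    a trait arrow approximates their correlation.
    """

    canonical_eigenvalues: np.ndarray
    pct_of_total: np.ndarray
    total_variance: float
    constrained_variance: float
    axis_scores: pd.DataFrame
    env_scores: pd.DataFrame
    trait_scores: pd.DataFrame
    perm_test: dict | None = None


def _center(A: np.ndarray) -> np.ndarray:
    return A - A.mean(axis=0)


def rda(traits: pd.DataFrame, env: pd.DataFrame) -> RDAResult:
    """Redundancy analysis: PCA of traits fitted on environment.

    ``traits`` (n x m) and ``env`` (n x q) must cover the same
    individuals in the same order; both are centered internally (pass
    standardized matrices for a correlation-scale analysis).  ``env``
    must have full column rank.
    """
    if len(traits) != len(env):
        raise ValueError("traits and env cover different numbers of individuals")
    Y = _center(np.asarray(traits, dtype=float))
    Xc = _center(np.asarray(env, dtype=float))
    n, m = Y.shape
    q = Xc.shape[1]
    rank = np.linalg.matrix_rank(Xc)
    if rank < q:
        # name the offending columns via QR pivoting
        _, R, piv = sla.qr(Xc, pivoting=True, mode="economic")
        dependent = [env.columns[j] for j in piv[rank:]]
        raise ValueError(f"environment matrix is rank-deficient; dependent "
                         f"columns: {dependent}")

    B, *_ = np.linalg.lstsq(Xc, Y, rcond=None)
    Yhat = Xc @ B
    U, sv, Vt = np.linalg.svd(Yhat, full_matrices=False)
    n_axes = min(q, m)
    sv = sv[:n_axes]
    eig = sv**2 / (n - 1)
    total = float(np.sum(Y**2) / (n - 1))
    axes = [f"RDA{k + 1}" for k in range(n_axes)]

    site = pd.DataFrame(U[:, :n_axes] * sv, index=traits.index, columns=axes)
    env_scores = pd.DataFrame(_corr_with(Xc, site.to_numpy()),
                              index=env.columns, columns=axes)
    trait_scores = pd.DataFrame(_corr_with(Y, site.to_numpy()),
                                index=traits.columns, columns=axes)
    return RDAResult(
        canonical_eigenvalues=eig,
        pct_of_total=eig / total * 100.0,
        total_variance=total,
        constrained_variance=float(eig.sum()),
        axis_scores=site,
        env_scores=env_scores,
        trait_scores=trait_scores,
    )


def _corr_with(A: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Column-wise correlations of A's variables with each score axis."""
    Ac = _center(A)
    Sc = _center(scores)
    num = Ac.T @ Sc
    denom = np.outer(np.linalg.norm(Ac, axis=0), np.linalg.norm(Sc, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / denom
    return np.where(np.isfinite(out), out, 0.0)


def rda_permutation_test(
    traits: pd.DataFrame,
    env: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> dict:
    """Permutation test of the RDA's overall constraint.

    pseudo-F = (constrained variance / q) / (residual variance /
    (n - q - 1)); the rows of ``env`` are permuted ``n_perm`` times and
    p = (1 + #{F* >= F}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Y = _center(np.asarray(traits, dtype=float))
    Xc = _center(np.asarray(env, dtype=float))
    n, q = Xc.shape
    Q, _ = np.linalg.qr(Xc)
    ss_total = float(np.sum(Y**2))

    def pseudo_f(Yc: np.ndarray) -> float:
        ss_fit = float(np.sum((Q.T @ Yc) ** 2))
        ss_res = ss_total - ss_fit
        return (ss_fit / q) / (ss_res / (n - q - 1))

    f_obs = pseudo_f(Y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        # permuting rows of env == inversely permuting rows of Y
        count += pseudo_f(Y[rng.permutation(n)]) >= f_obs
    p = (1.0 + count) / (1.0 + n_perm)
    return {"F": f_obs, "p": p, "n_perm": n_perm}


def forward_select(
    traits: pd.DataFrame,
    env: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
) -> list[str]:
    """Forward selection of environment variables by permutation p-value.

    Variables are added one at a time (largest drop in residual variance
    first) while the added variable's marginal permutation test on the
    current residuals stays below ``alpha``.  Used to decide which
    microhabitat arrows a triplot retains.
    """
    rng = np.random.default_rng(seed)
    selected: list[str] = []
    remaining = list(env.columns)
    Yres = _center(np.asarray(traits, dtype=float))
    while remaining:
        best_var, best_fit = None, -np.inf
        for v in remaining:
            x = _center(env[[v]].to_numpy(dtype=float))
            Qv, _ = np.linalg.qr(x)
            ss_fit = float(np.sum((Qv.T @ Yres) ** 2))
            if ss_fit > best_fit:
                best_var, best_fit = v, ss_fit
        test = rda_permutation_test(
            pd.DataFrame(Yres), env[[best_var]], n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
        if test["p"] >= alpha:
            break
        selected.append(best_var)
        remaining.remove(best_var)
        x = _center(env[[best_var]].to_numpy(dtype=float))
        Qv, _ = np.linalg.qr(x)
        Yres = Yres - Qv @ (Qv.T @ Yres)
    return selected
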