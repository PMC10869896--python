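"""PCA functional space built from standardized traits.

The multidimensional functional space is the span of the principal axes of
the trait correlation matrix whose eigenvalues exceed 1 (Kaiser rule).
Individuals are points (their axis scores); trait-axis Pearson
correlations describe what each axis means biologically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traits import TraitMatrix

__all__ = ["FunctionalSpace", "build_space", "trait_axis_correlations"]

#: tolerance guard so an eigenvalue of exactly 1.0 is retained
_KAISER_GUARD = 1e-12


@dataclass
class FunctionalSpace:
    """Retained principal axes of the trait correlation matrix.

    Attributes
    ----------
    eigenvalues : all eigenvalues, nonincreasing; they sum to the number
        of traits (correlation-matrix PCA).
    retained_axes : number of eigenvalues > 1.
    explained_pct : percent of total trait variance per axis (all axes).
    coordinates : individuals x retained axes scores (columns PC1..PCk).
    loadings : traits x retained axes Pearson correlations.
    components : unit eigenvectors (traits x retained axes), sign-fixed.
    """

    eigenvalues: np.ndarray
    retained_axes: int
    explained_pct: np.ndarray
    coordinates: pd.DataFrame
    loadings: pd.DataFrame
    components: pd.DataFrame = field(repr=False)


def build_space(traits: TraitMatrix) -> FunctionalSpace:
    """Eigendecompose the trait correlation matrix and score individuals.

    Requires a standardized trait matrix with n >= p + 1 individuals.
    Axis signs follow a fixed convention: each axis is oriented so that
    the trait with the largest absolute loading loads positively (PCA
    signs are otherwise arbitrary).

    Raises
    ------
    ValueError
        If the matrix is not standardized, n is too small, or the
        correlation matrix is singular.
    """
    if not traits.standardized:
        raise ValueError("build_space expects a standardized trait matrix")
    Z = traits.values
    n, p = Z.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} individuals for {p} traits; got {n}")

    R = (Z.T @ Z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    if eigvals[-1] < 1e-10:
        raise ValueError("singular trait correlation matrix (collinear traits)")

    retained = int(np.sum(eigvals > 1.0 - _KAISER_GUARD))
    V = eigvecs[:, :retained]
    lam = eigvals[:retained]

    # sign convention: largest-|loading| trait of each axis loads positively
    loadings = V * np.sqrt(lam)  # exact Pearson r for ddof=1 z-scores
    for k in range(retained):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            V[:, k] = -V[:, k]
            loadings[:, k] = -loadings[:, k]

    axes = [f"PC{k + 1}" for k in range(retained)]
    scores = pd.DataFrame(Z @ V, index=traits.ids, columns=axes)
    return FunctionalSpace(
        eigenvalues=eigvals,
        retained_axes=retained,
        explained_pct=eigvals / p * 100.0,
        coordinates=scores,
        loadings=pd.DataFrame(loadings, index=traits.data.columns, columns=axes),
        components=pd.DataFrame(V, index=traits.data.columns, columns=axes),
    )


def trait_axis_correlations(space: FunctionalSpace, traits: TraitMatrix) -> pd.DataFrame:
    """Pearson r between every trait and every retained axis, with p-values.

    Recomputed directly from the data (not from the eigenvectors), so it
    doubles as a consistency check on the loadings; the two agree to
    numerical precision when ``space`` was built from ``traits``.

    Returns a DataFrame indexed by trait with columns ``(axis, "r")`` and
    ``(axis, "p")``.
    """
    from scipy import stats

    if not traits.ids.equals(space.coordinates.index):
        raise ValueError("trait matrix and functional space cover different individuals")
    out: dict[tuple[str, str], pd.Series] = {}
    for axis in space.coordinates.columns:
        s = space.coordinates[axis].to_numpy()
        rs, ps = [], []
        for trait in traits.data.columns:
            r, p = stats.pearsonr(traits.data[trait].to_numpy(), s)
            rs.append(r)
            ps.append(p)
        out[(axis, "r")] = pd.Series(rs, index=traits.data.columns)
        out[(axis, "p")] = pd.Series(ps, index=traits.data.columns)
    return pd.DataFrame(out)
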