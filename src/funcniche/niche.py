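"""Functional-niche metrics in the PC trait space.

Three complementary indices describe how demographic groups (juveniles,
males, females) occupy the functional space:

* **FIde** (functional identity): the abundance-weighted mean position of
  a group on each retained axis.
* **FRic** (functional richness): the convex-hull volume of a group,
  expressed as a percentage of the pooled (all-individuals) hull volume.
* **FOve** (functional overlap): the Jaccard ratio of two groups' hull
  volumes, intersection / union.

Because observed FRic and FOve grow with sample size, both are also
bootstrapped by subsampling every group down to a common n (without
replacement) and taking percentile confidence intervals across
replicates.  Group position differences are tested with a one-way
PERMANOVA on Euclidean distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np

from .geometry import hull_intersection_volume, hull_volume

__all__ = [
    "BootstrapResult",
    "PermanovaResult",
    "fide",
    "fric",
    "fove",
    "bootstrap_metric",
    "permanova",
]

logger = logging.getLogger(__name__)


def fide(coordinates: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Abundance-weighted mean position of a group on each axis.

    Unit weights by default (each individual counts once).  Weights must
    be nonnegative with a positive sum.
    """
    pts = np.asarray(coordinates, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if weights is None:
        weights = np.ones(len(pts))
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != pts.shape[0]:
        raise ValueError("weights length must match number of individuals")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    return (w[:, None] * pts).sum(axis=0) / w.sum()


def fric(group_points: np.ndarray, pooled_points: np.ndarray) -> float:
    """Group convex-hull volume as % of the pooled-hull volume."""
    v_pool = hull_volume(pooled_points)
    if v_pool <= 0:
        raise ValueError("pooled hull is degenerate (zero volume)")
    return 100.0 * hull_volume(group_points) / v_pool


def fove(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Functional overlap: intersection volume / union volume, in [0, 1].

    Union volume comes from inclusion-exclusion, V(A) + V(B) - V(A&B).
    Both hulls must have positive volume.
    """
    v_a = hull_volume(points_a)
    v_b = hull_volume(points_b)
    if v_a <= 0 or v_b <= 0:
        raise ValueError("fove requires both hulls to have positive volume")
    v_int = hull_intersection_volume(points_a, points_b)
    ratio = v_int / (v_a + v_b - v_int)
    # clamp numerical fuzz at the boundaries
    return float(min(max(ratio, 0.0), 1.0))


@dataclass
class BootstrapResult:
    """Percentile CI of a subsampled niche metric."""

    label: str
    metric: str
    subsample_n: int
    n_reps: int
    ci_low: float
    ci_high: float
    median: float
    seed: int | None
    values: np.ndarray | None = None


def bootstrap_metric(
    points_by_group: Mapping[str, np.ndarray],
    metric: str,
    subsample_n: int,
    n_reps: int = 10_000,
    seed: int | None = None,
    pooled_points: np.ndarray | None = None,
    with_replacement: bool = False,
    keep_values: bool = False,
) -> dict[str, BootstrapResult]:
    """Bootstrap FRic or FOve at a common subsample size.

    For ``metric="fric"`` each eligible group is subsampled to
    ``subsample_n`` individuals ``n_reps`` times and FRic recomputed
    against the fixed pooled hull of all individuals.  For
    ``metric="fove"`` each eligible *pair* of groups is subsampled.  A
    group at or below ``subsample_n`` cannot be strictly subsampled and
    is skipped with a logged notice; pairs require both members eligible.

    Resampling is without replacement by default (subsampling); set
    ``with_replacement=True`` for a classical bootstrap.

    Returns a mapping from group (or "A|B" pair) label to
    :class:`BootstrapResult`, containing the 2.5th/97.5th percentile
    interval.
    """
    if metric not in ("fric", "fove"):
        raise ValueError(f"unknown metric {metric!r}; expected 'fric' or 'fove'")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    groups = {g: np.asarray(p, dtype=float) for g, p in points_by_group.items()}
    rng = np.random.default_rng(seed)

    def draw(pts: np.ndarray) -> np.ndarray:
        idx = rng.choice(len(pts), size=subsample_n, replace=with_replacement)
        return pts[idx]

    eligible = {}
    for g, pts in groups.items():
        if len(pts) > subsample_n:
            eligible[g] = pts
        else:
            logger.info(
                "bootstrap %s: group %r (n=%d) skipped at subsample_n=%d",
                metric, g, len(pts), subsample_n,
            )

    results: dict[str, BootstrapResult] = {}
    if metric == "fric":
        if pooled_points is None:
            pooled_points = np.vstack(list(groups.values()))
        for g, pts in eligible.items():
            vals = np.array([fric(draw(pts), pooled_points) for _ in range(n_reps)])
            results[g] = _summarize(g, metric, subsample_n, n_reps, seed, vals,
                                    keep_values)
    else:
        for ga, gb in combinations(sorted(eligible), 2):
            vals = np.array(
                [fove(draw(eligible[ga]), draw(eligible[gb])) for _ in range(n_reps)]
            )
            results[f"{ga}|{gb}"] = _summarize(
                f"{ga}|{gb}", metric, subsample_n, n_reps, seed, vals, keep_values
            )
    return results


def _summarize(label, metric, subsample_n, n_reps, seed, vals, keep_values):
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return BootstrapResult(
        label=label, metric=metric, subsample_n=subsample_n, n_reps=n_reps,
        ci_low=float(lo), ci_high=float(hi), median=float(np.median(vals)),
        seed=seed, values=vals if keep_values else None,
    )


@dataclass
class PermanovaResult:
    pseudo_F: float
    p: float
    n_perm: int


def _ss_within(d2: np.ndarray, onehots: list[np.ndarray], sizes: np.ndarray) -> np.ndarray:
    """Within-group sum of squares for a batch of label assignments.

    ``onehots[g]`` is a (B, n) 0/1 matrix marking membership of group g in
    each of B assignments; SS_w = sum_g (1/n_g) * sum_{i<j in g} d2_ij.
    """
    ssw = np.zeros(onehots[0].shape[0])
    for m, n_g in zip(onehots, sizes):
        ssw += np.einsum("bi,ij,bj->b", m, d2, m) / (2.0 * n_g)
    return ssw


def permanova(
    coordinates: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on Euclidean distances among axis coordinates.

    pseudo-F = (SS_between / (g - 1)) / (SS_within / (n - g)), with the
    sums of squares computed from pairwise squared distances; the p-value
    permutes group labels and uses the add-one convention,
    p = (1 + #{F* >= F}) / (1 + n_perm), so it is never exactly zero.
    """
    pts = np.asarray(coordinates, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    labels = np.asarray(labels)
    if len(labels) != len(pts):
        raise ValueError("labels and coordinates disagree in length")
    uniq, codes = np.unique(labels, return_inverse=True)
    g = len(uniq)
    if g < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        small = uniq[sizes < 2].tolist()
        raise ValueError(f"every group needs >= 2 members; too small: {small}")
    n = len(pts)

    sq = np.sum(pts**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (pts @ pts.T)
    np.fill_diagonal(d2, 0.0)
    d2 = np.maximum(d2, 0.0)

    ss_total = d2.sum() / (2.0 * n)
    obs_onehots = [(codes == k)[None, :].astype(float) for k in range(g)]
    ss_w = _ss_within(d2, obs_onehots, sizes)[0]
    ss_b = ss_total - ss_w
    f_obs = (ss_b / (g - 1)) / (ss_w / (n - g))

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
    perm_onehots = [(perms == k).astype(float) for k in range(g)]
    ss_w_perm = _ss_within(d2, perm_onehots, sizes)
    f_perm = ((ss_total - ss_w_perm) / (g - 1)) / (ss_w_perm / (n - g))
    p = (1.0 + np.sum(f_perm >= f_obs)) / (1.0 + n_perm)
    return PermanovaResult(pseudo_F=float(f_obs), p=float(p), n_perm=n_perm)
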