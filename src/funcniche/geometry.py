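"""Exact convex-hull geometry in low-dimensional trait spaces.

These are the geometric primitives behind convex-hull functional richness
(FRic) and functional overlap (FOve): the d-dimensional Lebesgue volume of
a point cloud's convex hull, and the exact volume of the intersection of
two hulls.

Intersections are computed exactly, not by Monte Carlo: the facet
half-spaces of both hulls are pooled, a strictly interior point of the
intersection polytope is located as the Chebyshev center of the pooled
system (a linear program), and the intersection's vertices are enumerated
with Qhull's half-space intersection.  This is cheap for the hull sizes
that arise in practice (tens of individuals in a 2-4 dimensional PC
space).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError

__all__ = ["hull_volume", "hull_intersection_volume", "chebyshev_center"]


def _validate_points(points: np.ndarray, name: str = "points") -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array (n points x d dimensions)")
    if pts.shape[1] < 2:
        raise ValueError(
            f"{name} must have dimension d >= 2; got d={pts.shape[1]}"
        )
    if not np.all(np.isfinite(pts)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return pts


def hull_volume(points: np.ndarray) -> float:
    """d-dimensional volume of the convex hull of ``points``.

    Returns 0.0 for degenerate sets: fewer than d+1 points, or points that
    are affinely dependent (hull flat in some direction).

    Parameters
    ----------
    points : (n, d) array_like
        Point coordinates, d >= 2, all finite.
    """
    pts = _validate_points(points)
    n, d = pts.shape
    if n < d + 1:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        # affinely dependent input: flat hull, zero d-volume
        return 0.0


def chebyshev_center(halfspaces: np.ndarray) -> tuple[np.ndarray, float]:
    """Chebyshev center (deepest interior point) of ``{x : A x + b <= 0}``.

    ``halfspaces`` is in Qhull's stacked form ``[A | b]``.  Returns the
    center and its radius; the radius is negative or the LP is infeasible
    when the polytope is empty.
    """
    halfspaces = np.asarray(halfspaces, dtype=float)
    A = halfspaces[:, :-1]
    b = halfspaces[:, -1]
    d = A.shape[1]
    norms = np.linalg.norm(A, axis=1, keepdims=True)
    # maximize r subject to A x + r*||a_i|| <= -b
    c = np.zeros(d + 1)
    c[-1] = -1.0
    A_ub = np.hstack([A, norms])
    res = linprog(c, A_ub=A_ub, b_ub=-b, bounds=[(None, None)] * d + [(0, None)],
                  method="highs")
    if not res.success:
        return np.full(d, np.nan), -np.inf
    return res.x[:-1], float(res.x[-1])


def hull_intersection_volume(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Exact volume of the intersection of two convex hulls.

    Both point sets must span full dimension (non-degenerate hulls);
    degenerate input raises, because a flat hull has zero volume and the
    caller should apply the FRic = 0 convention directly instead of
    intersecting it.  Disjoint hulls return 0.0.
    """
    pts_a = _validate_points(points_a, "points_a")
    pts_b = _validate_points(points_b, "points_b")
    if pts_a.shape[1] != pts_b.shape[1]:
        raise ValueError("point sets must live in the same dimension")
    try:
        hull_a = ConvexHull(pts_a)
        hull_b = ConvexHull(pts_b)
    except QhullError as exc:
        raise ValueError(
            "degenerate input hull (affinely dependent points); a flat hull "
            "has zero volume - use the FRic = 0 convention instead of "
            "intersecting it"
        ) from exc

    halfspaces = np.vstack([hull_a.equations, hull_b.equations])
    center, radius = chebyshev_center(halfspaces)
    # scale-aware threshold: an intersection thinner than ~1e-12 of the
    # coordinate scale is measure-zero contact, not overlap
    scale = max(1.0, np.abs(np.vstack([pts_a, pts_b])).max())
    if not np.isfinite(radius) or radius <= 1e-12 * scale:
        return 0.0
    try:
        hsi = HalfspaceIntersection(halfspaces, center)
        return float(ConvexHull(hsi.intersections).volume)
    except QhullError:
        return 0.0
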