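"""Independent test oracles.

Monte-Carlo rejection-sampling estimates of hull and intersection
volumes, and a brute-force Shapley-value hierarchical partition.  These
deliberately avoid the code paths they check: containment is tested via
Qhull facet equations only (no volume calls), partitioning enumerates
predictor orderings with plain least squares.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy.spatial import ConvexHull

CHUNK = 200_000


def _contains(hull: ConvexHull, pts: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    A = hull.equations[:, :-1]
    b = hull.equations[:, -1]
    return (pts @ A.T + b <= tol).all(axis=1)


def mc_hull_volume(points: np.ndarray, n_samples: int, rng: np.random.Generator):
    """Rejection-sampling estimate of hull volume and its Monte-Carlo SE."""
    hull = ConvexHull(points)
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    box = float(np.prod(hi - lo))
    hits = 0
    remaining = n_samples
    while remaining > 0:
        m = min(CHUNK, remaining)
        pts = rng.uniform(lo, hi, size=(m, points.shape[1]))
        hits += int(_contains(hull, pts).sum())
        remaining -= m
    p = hits / n_samples
    est = box * p
    se = box * np.sqrt(p * (1 - p) / n_samples)
    return est, se


def mc_intersection_volume(points_a: np.ndarray, points_b: np.ndarray,
                           n_samples: int, rng: np.random.Generator):
    """Rejection-sampling estimate of the hull-intersection volume."""
    hull_a = ConvexHull(points_a)
    hull_b = ConvexHull(points_b)
    lo = np.maximum(points_a.min(axis=0), points_b.min(axis=0))
    hi = np.minimum(points_a.max(axis=0), points_b.max(axis=0))
    if np.any(hi <= lo):
        return 0.0, 0.0
    box = float(np.prod(hi - lo))
    hits = 0
    remaining = n_samples
    while remaining > 0:
        m = min(CHUNK, remaining)
        pts = rng.uniform(lo, hi, size=(m, points_a.shape[1]))
        hits += int((_contains(hull_a, pts) & _contains(hull_b, pts)).sum())
        remaining -= m
    p = hits / n_samples
    return box * p, box * np.sqrt(p * (1 - p) / n_samples)


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    design = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_res = float(resid @ resid)
    yc = y - y.mean()
    return 1.0 - ss_res / float(yc @ yc)


def shapley_partition_r2(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Independent contributions of each column of X to the OLS R^2,
    averaged over every ordering of predictor entry (Shapley value)."""
    p = X.shape[1]
    contrib = np.zeros(p)
    orders = list(permutations(range(p)))
    for order in orders:
        so_far: list[int] = []
        prev = 0.0
        for j in order:
            so_far.append(j)
            cur = _ols_r2(y, X[:, so_far])
            contrib[j] += cur - prev
            prev = cur
    return contrib / len(orders)
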