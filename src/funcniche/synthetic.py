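"""Synthetic lizard populations and transect environments.

The generator reproduces the statistical structure the analysis assumes,
so every downstream stage is testable without field data:

* three demographic groups (40 juveniles, 30 males, 41 females by
  default) whose latent functional-trait centroids are separated by a
  configurable number of trait standard deviations along fixed ontogeny
  and sex contrasts, then back-transformed into positive raw
  morphometrics through the trait formulas;
* 11 transects with 11 environmental variables drawn from a multivariate
  Gaussian whose correlation matrix embeds the strong surface-ground /
  soil temperature correlation (r = 0.958) and the negative bare-soil /
  clumping-grass coverage correlation (r = -0.907); coverages are
  simulated on the logit scale and mapped to [0, 100]% so the bounds are
  respected by construction;
* per-transect, per-group capture counts driven by a log-link linear
  predictor on the standardized environments (Poisson by default).

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .habitat import ENV_VARS
from .traits import GROUPS

__all__ = [
    "SimulationConfig",
    "generate_individuals",
    "generate_environments",
    "generate_counts",
    "generate_dataset",
]


def _default_group_sizes() -> dict[str, int]:
    return {"juvenile": 40, "male": 30, "female": 41}


def _default_glm_coefficients() -> dict[str, dict[str, float]]:
    # sign pattern of the habitat preferences the count models should
    # recover: adults avoid bright transects, males avoid clumping grass,
    # juveniles track warm dry soil
    return {
        "female": {"Illu": -0.6},
        "male": {"Illu": -0.4, "CGC": -0.6},
        "juvenile": {"ST": 0.6, "SH": -0.5},
    }


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic population.

    ``trait_centroid_shift`` is the distance (in trait SD units) between
    the juvenile and adult latent trait centroids; 0 yields a single
    homogeneous population (the null case for group-difference tests).
    """

    n_transects: int = 11
    group_sizes: Mapping[str, int] = field(default_factory=_default_group_sizes)
    trait_centroid_shift: float = 2.0
    env_corr_temp: float = 0.958
    env_corr_cover: float = -0.907
    glm_coefficients: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_glm_coefficients)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transects < 2:
            raise ValueError("n_transects must be >= 2")
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}; allowed: {GROUPS}")
            if n <= 0:
                raise ValueError(f"group size for {g!r} must be positive")
        for name in ("env_corr_temp", "env_corr_cover"):
            if abs(getattr(self, name)) > 1:
                raise ValueError(f"|{name}| must be <= 1")


# latent-trait baselines for an adult female: (mean, SD) per free trait.
# LR is not free - it equals RFL/RHL by construction.
_BASELINE = {
    "Mass": (0.92, 0.06),   # log10(g + 1); ~7.3 g adults
    "EP":   (0.60, 0.040),
    "MS":   (0.55, 0.035),
    "HS":   (8.50, 0.45),   # mm (geometric-mean head dimension)
    "RFL":  (0.40, 0.022),
    "RHL":  (0.60, 0.030),
    "RTL":  (1.20, 0.070),
    "RAW":  (0.26, 0.018),
}
_FREE_TRAITS = list(_BASELINE)

# ontogeny contrast (juveniles positive): lighter, smaller-headed, with
# relatively longer limbs and tails, wider-set eyes, narrower abdomen
_U_ONTOGENY = {
    "Mass": -0.45, "EP": 0.30, "MS": 0.10, "HS": -0.45,
    "RFL": 0.30, "RHL": 0.40, "RTL": 0.25, "RAW": -0.30,
}
# sex contrast (females positive): heavier, wider abdomen, shorter tail
_U_SEX = {
    "Mass": 0.35, "EP": 0.0, "MS": -0.20, "HS": 0.25,
    "RFL": -0.15, "RHL": -0.20, "RTL": -0.45, "RAW": 0.60,
}


def _unit(d: dict[str, float]) -> np.ndarray:
    v = np.array([d[t] for t in _FREE_TRAITS])
    return v / np.linalg.norm(v)


# group positions along (ontogeny, sex), in units of trait_centroid_shift
_GROUP_POSITIONS = {
    "juvenile": (1.0, 0.0),
    "male": (0.0, -0.25),
    "female": (0.0, 0.25),
}


def generate_individuals(
    config: SimulationConfig,
    transect_weights: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Simulate one row per individual: id, transect, group, morphometrics.

    Latent functional traits are drawn per group around shifted centroids
    and back-transformed to raw measurements (mm, g); all lengths are
    positive by construction, and juvenile SVL stays below 40 mm (the
    field criterion separating juveniles from adults).

    ``transect_weights`` optionally gives per-group assignment
    probabilities over transects (default: uniform).
    """
    rng = np.random.default_rng([config.seed, 101])
    u1, u2 = _unit(_U_ONTOGENY), _unit(_U_SEX)
    sd = np.array([_BASELINE[t][1] for t in _FREE_TRAITS])
    mean = np.array([_BASELINE[t][0] for t in _FREE_TRAITS])

    rows = []
    for group in GROUPS:
        n = int(config.group_sizes.get(group, 0))
        if n == 0:
            continue
        a, b = _GROUP_POSITIONS[group]
        offset = config.trait_centroid_shift * (a * u1 + b * u2)
        z = rng.standard_normal((n, len(_FREE_TRAITS))) + offset
        lat = mean + sd * z
        # keep every latent trait safely positive
        lat = np.maximum(lat, 0.05 * mean)
        traits = pd.DataFrame(lat, columns=_FREE_TRAITS)

        if group == "juvenile":
            svl = np.clip(rng.normal(32.0, 3.0, n), 22.0, 39.5)
        else:
            svl = np.clip(rng.normal(56.0, 3.5, n), 42.0, 70.0)
        # head shape ratios vary mildly and independently of head size
        ra = rng.normal(1.30, 0.04, n)
        rb = rng.normal(0.65, 0.03, n)
        # invert HS = (HW*HL*HH)^(1/3) given the shape ratios, so the
        # latent head size is reproduced exactly; group size structure
        # enters only through the latent centroid shift (at shift 0 the
        # groups are exchangeable in trait space by construction)
        hw = traits["HS"] / np.cbrt(ra * rb)

        morph = pd.DataFrame({
            "group": group,
            "M": np.maximum(10.0 ** traits["Mass"] - 1.0, 0.0),
            "IO": traits["EP"] * hw,
            "MW": traits["MS"] * hw,
            "HL": ra * hw,
            "HH": rb * hw,
            "HW": hw,
            "FLL": traits["RFL"] * svl,
            "HLL": traits["RHL"] * svl,
            "TAL": traits["RTL"] * svl,
            "AMW": traits["RAW"] * svl,
            "SVL": svl,
        })
        rows.append(morph)

    df = pd.concat(rows, ignore_index=True)
    df.insert(0, "id", [f"L{i + 1:03d}" for i in range(len(df))])

    transects = [f"T{i + 1:02d}" for i in range(config.n_transects)]
    assigned = []
    for group in GROUPS:
        n = int(config.group_sizes.get(group, 0))
        if n == 0:
            continue
        if transect_weights is not None and group in transect_weights:
            w = np.asarray(transect_weights[group], dtype=float)
            w = w / w.sum()
        else:
            w = np.full(len(transects), 1.0 / len(transects))
        assigned.extend(rng.choice(transects, size=n, p=w))
    df.insert(1, "transect", assigned)
    return df


def _expit_corr(rho: float, loc1: float, s1: float, loc2: float, s2: float,
                n_nodes: int = 40) -> float:
    """Correlation of expit(loc + s*Z) pairs under latent correlation rho,
    by Gauss-Hermite quadrature."""
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    z = np.sqrt(2.0) * x
    p = w / np.sqrt(np.pi)
    g1 = expit(loc1 + s1 * z)
    m1, v1 = p @ g1, p @ g1**2 - (p @ g1) ** 2
    # Z2 = rho*Z1 + sqrt(1-rho^2)*Z2'
    z2 = rho * z[:, None] + np.sqrt(max(1 - rho**2, 0.0)) * z[None, :]
    g2_grid = expit(loc2 + s2 * z2)
    m2 = float(p @ (g2_grid @ p))
    v2 = float(p @ (g2_grid**2 @ p)) - m2**2
    e12 = float(p @ (g1 * (g2_grid @ p)))
    if v1 <= 0 or v2 <= 0:
        return 0.0
    return (e12 - m1 * m2) / np.sqrt(v1 * v2)


def _latent_cover_corr(target: float, loc1: float, s1: float,
                       loc2: float, s2: float) -> float:
    """Latent-scale correlation whose expit image has the target
    correlation (the logistic map attenuates correlations slightly)."""
    if target == 0.0:
        return 0.0
    lo, hi = (0.0, 1.0) if target > 0 else (-1.0, 0.0)
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        # the expit image correlation is increasing in the latent rho
        if _expit_corr(mid, loc1, s1, loc2, s2) < target:
            lo = mid
        else:
            hi = mid
    rho = 0.5 * (lo + hi)
    return float(np.clip(rho, -1.0, 1.0))


def _correlation_matrix(config: SimulationConfig) -> np.ndarray:
    corr = np.eye(len(ENV_VARS))
    i_sgt, i_st = ENV_VARS.index("SGT"), ENV_VARS.index("ST")
    i_bsc, i_cgc = ENV_VARS.index("BSC"), ENV_VARS.index("CGC")
    corr[i_sgt, i_st] = corr[i_st, i_sgt] = config.env_corr_temp
    rho_cover = _latent_cover_corr(config.env_corr_cover,
                                   _ENV_SCALE["BSC"][0], _ENV_SCALE["BSC"][1],
                                   _ENV_SCALE["CGC"][0], _ENV_SCALE["CGC"][1])
    corr[i_bsc, i_cgc] = corr[i_cgc, i_bsc] = rho_cover
    try:
        np.linalg.cholesky(corr + 1e-12 * np.eye(len(ENV_VARS)))
    except np.linalg.LinAlgError as exc:
        raise ValueError("requested environmental correlation matrix is not "
                         "positive semi-definite") from exc
    return corr


# per-variable location/scale on the simulation (latent) scale; the three
# coverages live on the logit scale and are mapped through expit * 100
_ENV_SCALE = {
    "AT":    (12.0, 3.0),    # deg C
    "AH":    (45.0, 8.0),    # %
    "SGT":   (22.0, 5.0),    # deg C
    "ST":    (16.0, 4.0),    # deg C
    "SH":    (18.0, 5.0),    # %
    "slope": (12.0, 5.0),    # degrees
    "aspect": (180.0, 70.0),  # degrees, treated as linear
    "Illu":  (60000.0, 15000.0),  # lux
    "RC":    (logit(0.20), 0.5),  # logit of proportion
    "BSC":   (logit(0.45), 0.5),
    "CGC":   (logit(0.40), 0.5),
}
_LOGIT_VARS = ("RC", "BSC", "CGC")


def generate_environments(config: SimulationConfig,
                          n_transects: int | None = None) -> pd.DataFrame:
    """Simulate the transect environment table.

    Returns one row per transect with the 11 microhabitat variables;
    coverages are percentages in [0, 100] by construction, slope and
    illuminance are clipped nonnegative, aspect to [0, 360).
    """
    n = config.n_transects if n_transects is None else int(n_transects)
    if n < 2:
        raise ValueError("need at least 2 transects")
    rng = np.random.default_rng([config.seed, 202])
    corr = _correlation_matrix(config)
    z = rng.multivariate_normal(np.zeros(len(ENV_VARS)), corr, size=n,
                                method="cholesky")
    env = pd.DataFrame(index=[f"T{i + 1:02d}" for i in range(n)])
    env.index.name = "transect"
    for j, var in enumerate(ENV_VARS):
        loc, scale = _ENV_SCALE[var]
        x = loc + scale * z[:, j]
        if var in _LOGIT_VARS:
            x = 100.0 * expit(x)
        elif var == "aspect":
            x = np.mod(x, 360.0)
        elif var in ("slope", "Illu", "AH", "SH"):
            x = np.maximum(x, 0.0)
        env[var] = x
    return env


def generate_counts(
    env: pd.DataFrame,
    coefficients: Mapping[str, float],
    family: str = "poisson",
    seed: int | None = None,
    dispersion: float = 1.0,
) -> np.ndarray:
    """Draw per-transect counts from a log-link linear predictor.

    ``coefficients`` maps predictor names (plus optional ``"intercept"``)
    to effects on the standardized (z-scored) environments.  ``family``
    is ``"poisson"`` or ``"negbin"`` (gamma-mixture with the given
    dispersion: variance = mu + dispersion * mu^2).
    """
    rng = np.random.default_rng(seed)
    eta = np.full(len(env), float(coefficients.get("intercept", 0.0)))
    for name, beta in coefficients.items():
        if name == "intercept":
            continue
        if name not in env.columns:
            raise ValueError(f"unknown predictor {name!r}; available: "
                             f"{list(env.columns)}")
        x = env[name].to_numpy(dtype=float)
        eta += float(beta) * (x - x.mean()) / x.std(ddof=1)
    mu = np.exp(eta)
    if family == "poisson":
        return rng.poisson(mu)
    if family == "negbin":
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mu / shape)
        return rng.poisson(lam)
    raise ValueError(f"unknown family {family!r}")


def generate_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full synthetic study: individuals plus transect table with counts.

    Environments are simulated first; each group's expected density per
    transect follows its log-link habitat model
    (``config.glm_coefficients``), individuals are assigned to transects
    with probabilities proportional to those densities, and the transect
    table records the resulting capture tallies.
    """
    env = generate_environments(config)
    weights = {}
    for group in GROUPS:
        coefs = dict(config.glm_coefficients.get(group, {}))
        eta = np.zeros(len(env))
        for name, beta in coefs.items():
            if name == "intercept":
                continue
            x = env[name].to_numpy(dtype=float)
            eta += float(beta) * (x - x.mean()) / x.std(ddof=1)
        weights[group] = np.exp(eta)
    individuals = generate_individuals(config, transect_weights=weights)

    transects = env.reset_index()
    tallies = individuals.groupby(["transect", "group"]).size().unstack(fill_value=0)
    for group in GROUPS:
        col = tallies[group] if group in tallies else pd.Series(0, index=tallies.index)
        transects[f"count_{group}"] = (
            transects["transect"].map(col).fillna(0).astype(int)
        )
    return individuals, transects
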