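"""Functional-trait construction from raw lizard morphometrics.

Ten linear measurements (mm) and body mass (g) are condensed into nine
unitless functional traits covering food acquisition and locomotion:

======  =============================  =========================================
trait   formula                        ecological reading
======  =============================  =========================================
Mass    log10(M + 1)                   volume / muscle mass
EP      IO / HW                        eye position - prey detection
MS      MW / HW                        mouth shape - prey size
HS      (HW * HL * HH) ** (1/3)        head size - bite performance
RFL     FLL / SVL                      relative forelimb length
RHL     HLL / SVL                      relative hindlimb length
LR      FLL / HLL                      limb ratio - coordination
RTL     TAL / SVL                      relative tail length
RAW     AMW / SVL                      relative abdominal width - fecundity
======  =============================  =========================================

All ratio traits are scale-free; Mass and HS are size traits by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "MORPHOMETRIC_COLUMNS",
    "TRAIT_NAMES",
    "TraitMatrix",
    "compute_traits",
    "standardize",
]

GROUPS = ("juvenile", "male", "female")

#: raw measurement columns expected on an individual table
MORPHOMETRIC_COLUMNS = [
    "M", "IO", "MW", "HL", "HH", "HW", "FLL", "HLL", "TAL", "AMW", "SVL",
]

TRAIT_NAMES = ["Mass", "EP", "MS", "HS", "RFL", "RHL", "LR", "RTL", "RAW"]


@dataclass
class TraitMatrix:
    """Individuals x traits, optionally z-scored.

    ``center`` and ``scale`` hold the per-trait constants used for
    standardization so the transform can be inverted exactly.
    """

    data: pd.DataFrame
    standardized: bool = False
    center: pd.Series | None = None
    scale: pd.Series | None = None

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def ids(self) -> pd.Index:
        return self.data.index

    def inverse(self) -> "TraitMatrix":
        """Undo standardization, recovering the raw trait values."""
        if not self.standardized:
            return TraitMatrix(self.data.copy(), standardized=False)
        raw = self.data * self.scale + self.center
        return TraitMatrix(raw, standardized=False)


def compute_traits(records: pd.DataFrame, log_base: float = 10.0) -> TraitMatrix:
    """Compute the nine functional traits from raw morphometrics.

    Parameters
    ----------
    records : DataFrame
        One row per individual; must contain :data:`MORPHOMETRIC_COLUMNS`.
        The index (or an ``id`` column) identifies individuals.
    log_base : float
        Base of the logarithm in the Mass trait, log(M + 1).  Base 10 is
        the morphometric convention.

    Raises
    ------
    ValueError
        On missing columns, or on zero/negative denominators, naming the
        offending individual and field.
    """
    df = records.set_index("id") if "id" in records.columns else records
    missing = [c for c in MORPHOMETRIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing morphometric columns: {missing}")

    bad: list[str] = []
    for col in ("HW", "SVL", "HLL"):
        offenders = df.index[df[col] <= 0]
        bad.extend(f"{ind}: {col} = {df.loc[ind, col]}" for ind in offenders)
    if bad:
        raise ValueError("non-positive denominator(s): " + "; ".join(map(str, bad)))
    if (df["M"] < 0).any():
        offenders = df.index[df["M"] < 0].tolist()
        raise ValueError(f"negative body mass for individuals {offenders}")

    traits = pd.DataFrame(index=df.index)
    traits["Mass"] = np.log(df["M"].astype(float) + 1.0) / np.log(log_base)
    traits["EP"] = df["IO"] / df["HW"]
    traits["MS"] = df["MW"] / df["HW"]
    traits["HS"] = np.cbrt(df["HW"] * df["HL"] * df["HH"])
    traits["RFL"] = df["FLL"] / df["SVL"]
    traits["RHL"] = df["HLL"] / df["SVL"]
    traits["LR"] = df["FLL"] / df["HLL"]
    traits["RTL"] = df["TAL"] / df["SVL"]
    traits["RAW"] = df["AMW"] / df["SVL"]
    return TraitMatrix(traits[TRAIT_NAMES], standardized=False)


def standardize(traits: TraitMatrix) -> TraitMatrix:
    """Z-score every trait column to mean 0, sample SD 1 (ddof = 1).

    Raises on fewer than two individuals or on a constant column (zero
    variance), naming the trait.
    """
    if traits.standardized:
        raise ValueError("trait matrix is already standardized")
    df = traits.data
    if len(df) < 2:
        raise ValueError("standardization needs at least 2 individuals")
    center = df.mean()
    scale = df.std(ddof=1)
    constant = scale.index[scale == 0].tolist()
    if constant:
        raise ValueError(f"constant trait column(s): {constant}")
    z = (df - center) / scale
    return TraitMatrix(z, standardized=True, center=center, scale=scale)
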