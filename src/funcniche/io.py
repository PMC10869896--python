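"""CSV readers/writers for the two input tables.

The individual table has one row per lizard::

    id,transect,group,M,IO,MW,HL,HH,HW,FLL,HLL,TAL,AMW,SVL

with ``group`` one of juvenile/male/female, mass ``M`` in grams and all
lengths in millimetres.  The transect table has one row per transect::

    transect,AT,AH,SGT,ST,SH,slope,aspect,Illu,RC,BSC,CGC,
    count_juvenile,count_male,count_female

All CSVs are UTF-8 with "." decimal and a mandatory header row.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .habitat import ENV_VARS
from .traits import GROUPS, MORPHOMETRIC_COLUMNS

__all__ = ["read_individuals", "read_transects", "write_individuals",
           "write_transects", "COUNT_COLUMNS"]

COUNT_COLUMNS = [f"count_{g}" for g in GROUPS]

_LENGTH_COLUMNS = [c for c in MORPHOMETRIC_COLUMNS if c != "M"]


def read_individuals(path: str | Path) -> pd.DataFrame:
    """Read and validate the individual table.

    Raises ``ValueError`` with the offending column or row number on a
    missing column, a duplicate id, an unknown group label, or a
    non-positive length measurement.
    """
    df = pd.read_csv(path, encoding="utf-8")
    required = ["id", "transect", "group"] + MORPHOMETRIC_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"individual table missing column(s): {missing}")
    dup = df["id"][df["id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate individual id(s): {dup.unique().tolist()}")
    bad_group = df.index[~df["group"].isin(GROUPS)]
    if len(bad_group):
        row = int(bad_group[0])
        raise ValueError(
            f"row {row + 2}: unknown group {df.loc[row, 'group']!r}; "
            f"allowed labels: {list(GROUPS)}"
        )
    for col in _LENGTH_COLUMNS:
        bad = df.index[df[col] <= 0]
        if len(bad):
            row = int(bad[0])
            raise ValueError(f"row {row + 2}: non-positive {col} "
                             f"({df.loc[row, col]})")
    if (df["M"] < 0).any():
        row = int(df.index[df["M"] < 0][0])
        raise ValueError(f"row {row + 2}: negative mass ({df.loc[row, 'M']})")
    return df


def read_transects(path: str | Path) -> pd.DataFrame:
    """Read and validate the transect table (environments + counts)."""
    df = pd.read_csv(path, encoding="utf-8")
    required = ["transect"] + ENV_VARS + COUNT_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"transect table missing column(s): {missing}")
    dup = df["transect"][df["transect"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate transect id(s): {dup.unique().tolist()}")
    for col in ("RC", "BSC", "CGC"):
        bad = df.index[(df[col] < 0) | (df[col] > 100)]
        if len(bad):
            row = int(bad[0])
            raise ValueError(f"row {row + 2}: coverage {col} outside [0, 100] "
                             f"({df.loc[row, col]})")
    for col in COUNT_COLUMNS:
        bad = df.index[df[col] < 0]
        if len(bad):
            row = int(bad[0])
            raise ValueError(f"row {row + 2}: negative count {col}")
    return df


def write_individuals(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["id", "transect", "group"] + MORPHOMETRIC_COLUMNS
    df[cols].to_csv(path, index=False, encoding="utf-8")


def write_transects(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["transect"] + ENV_VARS + COUNT_COLUMNS
    df[cols].to_csv(path, index=False, encoding="utf-8")
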