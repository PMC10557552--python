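"""Strict CSV readers and writers for paired series and station tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .rank_stats import PairedSeries
from .smoothing import STATION_COLUMNS

__all__ = ["read_pairs_csv", "write_pairs_csv", "read_station_csv"]


def _strict_numeric(col: pd.Series, name: str) -> np.ndarray:
    out = pd.to_numeric(col, errors="coerce")
    bad = out.isna() & col.notna() | col.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"column {name!r}: non-numeric or missing value at data row {row} "
            f"(value={col.iloc[row]!r})"
        )
    return out.to_numpy(dtype=float)


def read_pairs_csv(
    path,
    x_col: str | None = None,
    y_col: str | None = None,
    delimiter: str = ",",
    header: bool = True,
) -> PairedSeries:
    """Read a paired series from a delimited text file.

    With column names given, those two columns are used; otherwise the first
    two columns.  Parsing is strict: any non-numeric or missing cell raises
    with its row number instead of being dropped, since silent pairwise
    deletion would destroy the serial structure.
    """
    df = pd.read_csv(path, sep=delimiter, header=0 if header else None)
    if x_col is not None or y_col is not None:
        if x_col is None or y_col is None:
            raise ValueError("give both x_col and y_col, or neither")
        for c in (x_col, y_col):
            if c not in df.columns:
                raise ValueError(f"column {c!r} not found; available: {list(df.columns)}")
        xs, ys = df[x_col], df[y_col]
        names = (x_col, y_col)
    else:
        if df.shape[1] < 2:
            raise ValueError(f"need at least two columns, found {df.shape[1]}")
        xs, ys = df.iloc[:, 0], df.iloc[:, 1]
        names = (str(df.columns[0]), str(df.columns[1]))
    return PairedSeries(_strict_numeric(xs, names[0]), _strict_numeric(ys, names[1]))


def write_pairs_csv(p: PairedSeries, path) -> None:
    pd.DataFrame({"x": p.x, "y": p.y}).to_csv(path, index=False)


def read_station_csv(path, delimiter: str = ",") -> pd.DataFrame:
    """Read a tidy station table (station_id, year, a, b) with strict parsing."""
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in STATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"station CSV is missing columns {missing}")
    for c in ("year", "a", "b"):
        df[c] = _strict_numeric(df[c], c)
    df["year"] = df["year"].astype(int)
    return df[list(STATION_COLUMNS)]
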