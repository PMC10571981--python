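"""Reading and writing cow-record CSV files.

The interchange format is one CSV row per calving with the documented header:

    cow_id, herd, parity, parity_group, calving_date, bcs_calving,
    bcs_release, anestrus, metritis, mastitis, ai80, pre100, milk_kg, milk_dim

Dates are ISO-8601; BCS values must sit on the quarter-point grid in [1, 5]
(snapped when within 1e-9, rejected otherwise); outcomes are 0/1. Malformed
rows are rejected individually with their line number and reason, never
silently dropped.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .indicators import OUTCOMES

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("cow_id", "herd", "parity", "parity_group", "calving_date",
                    "bcs_calving", "bcs_release", *OUTCOMES, "milk_kg", "milk_dim")

GRID_TOL = 1e-9


def _on_grid(x: float) -> bool:
    return np.isfinite(x) and abs(x * 4 - round(x * 4)) <= 4 * GRID_TOL and 1.0 <= x <= 5.0


def read_cow_records(path: str | Path,
                     return_rejects: bool = False) -> pd.DataFrame | tuple[pd.DataFrame, list]:
    """Read and validate a cow-record CSV.

    Returns the validated table (typed columns, dates as ``datetime.date``).
    Rows failing validation are dropped with a logged line number and reason;
    pass ``return_rejects=True`` to also get the ``(line, reason)`` list.
    Raises on a missing mandatory column; an empty file yields an empty,
    correctly-typed table with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"cow_id": str, "herd": str, "parity_group": str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=REQUIRED_COLUMNS)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {missing}")
    if df.empty:
        warnings.warn(f"{path}: no data rows", RuntimeWarning, stacklevel=2)
        return (df, []) if return_rejects else df

    rejects: list[tuple[int, str]] = []
    keep = np.ones(len(df), dtype=bool)
    lines = df.index.to_numpy() + 2  # header is line 1

    dates = pd.to_datetime(df["calving_date"], errors="coerce", format="ISO8601")
    for i in np.flatnonzero(dates.isna().to_numpy()):
        rejects.append((int(lines[i]), f"unparseable calving_date {df['calving_date'].iloc[i]!r}"))
        keep[i] = False

    for col in ("bcs_calving", "bcs_release"):
        vals = pd.to_numeric(df[col], errors="coerce")
        for i in range(len(df)):
            if not keep[i]:
                continue
            v = vals.iloc[i]
            if pd.isna(v) or not _on_grid(float(v)):
                rejects.append((int(lines[i]),
                                f"{col}={df[col].iloc[i]!r} not on the quarter grid in [1, 5]"))
                keep[i] = False
        df[col] = np.round(vals.astype(float) * 4) / 4

    for col in OUTCOMES:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~vals.isin([0, 1]) & keep
        for i in np.flatnonzero(bad.to_numpy()):
            rejects.append((int(lines[i]), f"{col}={df[col].iloc[i]!r} not in {{0,1}}"))
            keep[i] = False
        df[col] = vals

    parity = pd.to_numeric(df["parity"], errors="coerce")
    bad = (parity.isna() | (parity < 1) | (parity != parity.round())).to_numpy() & keep
    for i in np.flatnonzero(bad):
        rejects.append((int(lines[i]), f"parity={df['parity'].iloc[i]!r} not a positive integer"))
        keep[i] = False

    for i in range(len(df)):
        if keep[i] and bool(parity.iloc[i] == 1) != (df["parity_group"].iloc[i] == "heifer"):
            rejects.append((int(lines[i]),
                            "parity_group inconsistent with parity (heifer iff parity == 1)"))
            keep[i] = False

    out = df[keep].copy()
    out["calving_date"] = dates[keep].dt.date
    out["parity"] = parity[keep].astype(int)
    for col in OUTCOMES:
        out[col] = out[col].astype(int)
    out["milk_kg"] = pd.to_numeric(out["milk_kg"], errors="coerce")
    out["milk_dim"] = pd.to_numeric(out["milk_dim"], errors="coerce")
    out = out.reset_index(drop=True)

    for line, reason in rejects:
        logger.warning("%s line %d rejected: %s", path.name, line, reason)
    return (out, rejects) if return_rejects else out


def write_cow_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write a cow-record table in the documented CSV dialect."""
    out = records.loc[:, list(REQUIRED_COLUMNS)].copy()
    out.to_csv(path, index=False)
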