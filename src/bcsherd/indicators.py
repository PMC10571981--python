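"""Derived body-condition indicators.

Computes the transition-period indicators used throughout the pipeline:

* ``delta_bcs`` — change in body condition score (BCS) between calving and
  reproductive release (scored 40-60 days in milk). Negative values are loss.
* ``exposure_flag`` — the binary "poor body condition" exposure: a cow that
  calves with BCS < 3 or loses more than 0.5 BCS points postpartum.
* ``season_of`` — Southern-hemisphere calving season on astronomical
  boundaries (summer starting 21 December, and so on by quarter).

All functions accept scalars or aligned pandas/numpy vectors. Missing scores
propagate as NaN; downstream stages exclude such records with a logged count
rather than imputing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Quarter-point step of the 5-point BCS scale.
BCS_GRID_STEP = 0.25

#: Southern-hemisphere seasons in reporting order (reference level first).
SEASONS = ("Summer", "Autumn", "Winter", "Spring")

#: Binary outcomes modelled at the cow level.
OUTCOMES = ("anestrus", "metritis", "mastitis", "ai80", "pre100")


@dataclass(frozen=True)
class ExposureRule:
    """Cut-offs defining the poor-body-condition exposure.

    A cow is exposed when ``bcs_calving < bcs_cut`` or its postpartum loss
    (``-delta_bcs``) exceeds ``loss_cut``. Both inequalities are strict, so a
    cow calving exactly at BCS 3.0 and losing exactly 0.5 is unexposed.
    """

    bcs_cut: float = 3.0
    loss_cut: float = 0.5

    def __post_init__(self) -> None:
        if not (1.0 < self.bcs_cut < 5.0):
            raise ValueError(f"bcs_cut must lie in (1, 5), got {self.bcs_cut}")
        if not (0.0 < self.loss_cut < 4.0):
            raise ValueError(f"loss_cut must lie in (0, 4), got {self.loss_cut}")


def delta_bcs(bcs_calving, bcs_release):
    """BCS at reproductive release minus BCS at calving (negative = loss)."""
    return np.subtract(bcs_release, bcs_calving)


def exposure_flag(bcs_calving, delta, rule: ExposureRule = ExposureRule()):
    """Binary poor-BCS exposure: BCS at calving < cut OR loss > cut.

    Parameters
    ----------
    bcs_calving : scalar or array
        BCS at calving on the 5-point quarter scale.
    delta : scalar or array
        Signed BCS change (release minus calving); loss is ``-delta``.
    rule : ExposureRule
        The two strict cut-offs.

    Returns
    -------
    0/1 (float NaN where either input is missing), same shape as the inputs.
    """
    b = np.asarray(bcs_calving, dtype=float)
    d = np.asarray(delta, dtype=float)
    flag = ((b < rule.bcs_cut) | (-d > rule.loss_cut)).astype(float)
    missing = np.isnan(b) | np.isnan(d)
    if np.ndim(flag) == 0:
        return float("nan") if missing else float(flag)
    flag = np.where(missing, np.nan, flag)
    if isinstance(bcs_calving, pd.Series):
        return pd.Series(flag, index=bcs_calving.index)
    return flag


# Season boundaries as (month, day) start dates; each season runs from its
# start date through the day before the next season's start. Summer wraps the
# year end, so it is handled via the month*100+day ordinal below.
_SEASON_STARTS = {"Summer": (12, 21), "Autumn": (3, 21), "Winter": (6, 21), "Spring": (9, 21)}


def season_of(date) -> str | pd.Series:
    """Southern-hemisphere season of a calendar date.

    Summer: 21 Dec - 20 Mar; Autumn: 21 Mar - 20 Jun; Winter: 21 Jun - 20 Sep;
    Spring: 21 Sep - 20 Dec. 29 February falls inside the summer interval.
    """
    if isinstance(date, (pd.Series, pd.DatetimeIndex, np.ndarray, list, tuple)):
        ts = pd.to_datetime(pd.Series(date) if not isinstance(date, pd.Series) else date)
        md = ts.dt.month * 100 + ts.dt.day
        out = pd.Series(np.select(
            [(md >= 1221) | (md <= 320), md <= 620, md <= 920, md <= 1220],
            ["Summer", "Autumn", "Winter", "Spring"], default="Summer",
        ), index=ts.index)
        return out
    d = pd.Timestamp(date)
    md = d.month * 100 + d.day
    if md >= 1221 or md <= 320:
        return "Summer"
    if md <= 620:
        return "Autumn"
    if md <= 920:
        return "Winter"
    return "Spring"


def add_indicators(records: pd.DataFrame, rule: ExposureRule = ExposureRule()) -> pd.DataFrame:
    """Return a copy of a cow-record table with derived indicator columns.

    Adds ``delta_bcs``, ``exposed``, ``year`` and ``season`` computed from
    ``bcs_calving``, ``bcs_release`` and ``calving_date``.
    """
    out = records.copy()
    out["delta_bcs"] = delta_bcs(out["bcs_calving"], out["bcs_release"])
    out["exposed"] = exposure_flag(out["bcs_calving"], out["delta_bcs"], rule)
    dates = pd.to_datetime(out["calving_date"])
    out["year"] = dates.dt.year
    out["season"] = season_of(dates)
    return out
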