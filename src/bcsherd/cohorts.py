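"""21-day calving cohorts.

Partitions calvings into consecutive 21-day bins (one estrous cycle) within
each herd × parity stratum, summarizes each cohort (size, poor-BCS exposure
prevalence, anestrus proportion, and pd — the exposed fraction among anestrus
cases), computes the quartiles of cohort exposure prevalence that are later
offered as screening thresholds, and labels cohorts as above / not above the
median anestrus proportion.

Cohorts with fewer than ``min_cohort_size`` calvings (default 20) are kept in
the summary table with ``included = False`` and excluded from quartiles,
median labelling and every downstream model.
"""

from __future__ import annotations

import logging
import warnings
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .indicators import ExposureRule, add_indicators

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 21
DEFAULT_MIN_COHORT = 20

_STRATUM = ["herd", "parity_group"]


def assign_cohorts(records: pd.DataFrame, origin: date | None = None,
                   window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Attach ``cohort_index`` and ``cohort_start`` to each record.

    ``cohort_index = floor((calving_date - origin) / window)`` with half-open
    bins ``[origin + k*window, origin + (k+1)*window)``. With ``origin=None``
    each herd × parity stratum is anchored at its own earliest calving date;
    a fixed calendar date applies to all strata and must not postdate any
    calving.
    """
    if window < 1:
        raise ValueError("window must be >= 1 day")
    out = records.copy()
    dates = pd.to_datetime(out["calving_date"])
    if origin is None:
        origins = dates.groupby([out[c] for c in _STRATUM]).transform("min")
    else:
        origins = pd.Series(pd.Timestamp(origin), index=out.index)
    offset_days = (dates - origins).dt.days
    if (offset_days < 0).any():
        bad = int((offset_days < 0).sum())
        raise ValueError(f"{bad} calvings precede the cohort origin")
    out["cohort_index"] = (offset_days // window).astype(int)
    out["cohort_start"] = (origins + pd.to_timedelta(out["cohort_index"] * window,
                                                     unit="D")).dt.date
    return out


def summarize_cohorts(records: pd.DataFrame, rule: ExposureRule = ExposureRule(),
                      min_cohort_size: int = DEFAULT_MIN_COHORT,
                      window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Per-cohort counts and proportions for every herd × parity stratum.

    Expects ``cohort_index`` from :func:`assign_cohorts`; computes exposure
    flags if the indicator columns are absent. Returns one row per cohort,
    including empty intermediate cohorts (n = 0), with columns: stratum keys,
    ``cohort_index``, ``date_start``/``date_end`` (half-open), ``n``,
    ``n_exposed``, ``exposure_prop``, ``n_anestrus``, ``anestrus_prop``,
    ``n_anestrus_exposed``, ``pd`` (NaN when there are no anestrus cases) and
    ``included`` (n >= min_cohort_size).
    """
    if "cohort_index" not in records.columns:
        raise ValueError("run assign_cohorts first (cohort_index missing)")
    if records.empty:
        warnings.warn("no records offered; empty cohort table", RuntimeWarning, stacklevel=2)
        return pd.DataFrame(columns=_STRATUM + [
            "cohort_index", "date_start", "date_end", "n", "n_exposed", "exposure_prop",
            "n_anestrus", "anestrus_prop", "n_anestrus_exposed", "pd", "included"])
    df = records
    if "exposed" not in df.columns or "delta_bcs" not in df.columns:
        df = add_indicators(df, rule)
        df["cohort_index"] = records["cohort_index"].to_numpy()
        df["cohort_start"] = records["cohort_start"].to_numpy()

    n_missing = int(df["exposed"].isna().sum() + df["anestrus"].isna().sum()
                    - (df["exposed"].isna() & df["anestrus"].isna()).sum())
    if n_missing:
        logger.info("summarize_cohorts: %d records missing exposure or outcome excluded",
                    n_missing)
    df = df.dropna(subset=["exposed", "anestrus"])

    df = df.assign(_anestrus_exposed=df["exposed"].to_numpy() * df["anestrus"].to_numpy())
    rows = []
    for (herd, pg), g in df.groupby(_STRATUM, sort=True):
        origin = pd.Timestamp(g["cohort_start"].min()) - pd.Timedelta(
            days=int(g["cohort_index"].min()) * window)
        counts = g.groupby("cohort_index").agg(
            n=("anestrus", "size"),
            n_exposed=("exposed", "sum"),
            n_anestrus=("anestrus", "sum"),
            n_anestrus_exposed=("_anestrus_exposed", "sum"),
        )
        for k in range(int(g["cohort_index"].max()) + 1):
            if k in counts.index:
                n, ne, na, nae = (int(counts.loc[k, c]) for c in
                                  ("n", "n_exposed", "n_anestrus", "n_anestrus_exposed"))
            else:
                n = ne = na = nae = 0
            start = (origin + pd.Timedelta(days=k * window)).date()
            rows.append({
                "herd": herd, "parity_group": pg, "cohort_index": k,
                "date_start": start, "date_end": start + timedelta(days=window),
                "n": n, "n_exposed": ne,
                "exposure_prop": ne / n if n else np.nan,
                "n_anestrus": na,
                "anestrus_prop": na / n if n else np.nan,
                "n_anestrus_exposed": nae,
                "pd": nae / na if na else np.nan,
                "included": n >= min_cohort_size,
            })
    out = pd.DataFrame(rows)
    n_excluded = int((~out["included"]).sum())
    if n_excluded:
        logger.info("summarize_cohorts: %d cohorts below the %d-calving minimum excluded",
                    n_excluded, min_cohort_size)
    return out


def cohort_quartiles(summaries: pd.DataFrame, method: str = "linear") -> tuple[float, float, float]:
    """Quartiles (Q25, Q50, Q75) of exposure prevalence over included cohorts.

    ``method`` is any numpy quantile method; the default ``"linear"`` is
    order-statistic type 7 (linear interpolation). Requires at least 4
    included cohorts.
    """
    props = summaries.loc[summaries["included"], "exposure_prop"].to_numpy(dtype=float)
    if len(props) < 4:
        stratum = summaries[_STRATUM].drop_duplicates().to_records(index=False).tolist() \
            if not summaries.empty else "empty"
        raise ValueError(f"need >= 4 included cohorts for quartiles; "
                         f"stratum {stratum} has {len(props)}")
    q25, q50, q75 = np.quantile(props, [0.25, 0.50, 0.75], method=method)
    return float(q25), float(q50), float(q75)


def median_split(summaries: pd.DataFrame) -> pd.Series:
    """High-anestrus label per included cohort: 1 iff strictly above the median.

    The median is the interpolated median of ``anestrus_prop`` over included
    cohorts; cohorts exactly at the median are labelled 0 ("not above").
    Returned Series is indexed like the included rows of ``summaries``.
    """
    inc = summaries[summaries["included"]]
    if len(inc) < 2:
        raise ValueError("need >= 2 included cohorts for a median split")
    med = float(np.median(inc["anestrus_prop"].to_numpy(dtype=float)))
    return (inc["anestrus_prop"] > med).astype(int)
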