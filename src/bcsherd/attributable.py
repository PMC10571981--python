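"""Adjusted risk ratios and the population attributable fraction (AF_P).

The population attributable fraction of anestrus due to poor body condition
is, per 21-day cohort,

    AF_P = pd * (aRR - 1) / aRR

where ``pd`` is the proportion of that cohort's anestrus cases that were
exposed (BCS < 3 at calving or loss > 0.5) and ``aRR`` is the adjusted risk
ratio of anestrus for exposed versus unexposed cows. Interpreted causally,
AF_P is the fraction of cases that would be avoided if no cow were exposed.

The adjusted model is a logistic regression of anestrus on the binary
exposure, calving year and calving season (plus parity 2/3/4+ in the
multiparous stratum), fitted per herd × parity stratum. A logistic
coefficient is an odds ratio, not a risk ratio, so by default the aRR is
obtained by marginal standardization (g-computation): the ratio of the mean
predicted risk with everyone set exposed to the mean predicted risk with
everyone set unexposed, averaged over the observed covariate distribution.
A compatibility mode ``"or-as-rr"`` reports exp(beta) directly instead.

The stratum-level aRR is combined with each cohort's own pd and anestrus
rate into the surveillance time series; a per-cohort-model variant exists
but cannot adjust for year/season (constant within a 21-day cohort) and is
flagged accordingly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .indicators import ExposureRule, add_indicators
from .models import SEPARATION_BOUND, _build_formula, _fit_logit, _subset_stratum

logger = logging.getLogger(__name__)

DEFAULT_N_BOOT = 500


@dataclass
class ArrEstimate:
    """Adjusted risk ratio of anestrus for exposed vs unexposed cows."""

    herd: object
    parity_group: object
    arr: float
    ci_low: float
    ci_high: float
    mode: str           # "standardized" | "or-as-rr"
    n_used: int
    n_boot: int
    converged: bool
    message: str = ""


def afp(pd_: float, arr: float) -> float:
    """Population attributable fraction ``pd * (arr - 1) / arr``.

    ``pd_`` is the exposed proportion among cases (in [0, 1]); ``arr`` must
    be positive. Negative values (protective exposure, arr < 1) are returned
    as-is, never clipped.
    """
    if not 0 <= pd_ <= 1:
        raise ValueError(f"pd must lie in [0, 1], got {pd_}")
    if not arr > 0:
        raise ValueError(f"aRR must be positive, got {arr}")
    return pd_ * (arr - 1.0) / arr


def _fit_and_standardize(data: pd.DataFrame, adjust: tuple[str, ...],
                         parity_group, mode: str) -> tuple[float, bool]:
    """One adjusted logistic fit -> aRR (standardized or exp(beta))."""
    formula, d, _ = _build_formula(data, "anestrus", ("exposed",), adjust, parity_group)
    res = _fit_logit(formula, d)
    ok = bool(res.mle_retvals.get("converged", False)) and \
        not np.any(np.abs(res.params.to_numpy()) > SEPARATION_BOUND)
    if mode == "or-as-rr":
        return float(np.exp(res.params["exposed"])), ok
    risk1 = float(res.predict(d.assign(exposed=1.0)).mean())
    risk0 = float(res.predict(d.assign(exposed=0.0)).mean())
    if risk0 == 0.0:
        raise ZeroDivisionError("zero predicted unexposed risk; aRR undefined")
    return risk1 / risk0, ok


def estimate_arr(records: pd.DataFrame, herd=None, parity_group=None,
                 rule: ExposureRule = ExposureRule(), mode: str = "standardized",
                 adjust: tuple[str, ...] = ("year", "season", "parity"),
                 n_boot: int = DEFAULT_N_BOOT, seed: int = 0,
                 min_cases: int = 10) -> ArrEstimate:
    """Adjusted risk ratio of anestrus for one herd × parity stratum.

    Fits anestrus ~ exposure + year + season (+ parity for multiparous) and
    standardizes to the observed covariate distribution (default mode). With
    no varying covariates the standardized aRR collapses exactly to the crude
    risk ratio. The CI is a seeded nonparametric percentile bootstrap over
    cows (``n_boot`` resamples; 0 skips the CI and reports NaN bounds).
    """
    if mode not in ("standardized", "or-as-rr"):
        raise ValueError(f"unknown aRR mode {mode!r}")
    data = _subset_stratum(records, herd, parity_group)
    if "exposed" not in data.columns:
        data = add_indicators(data, rule)
    data = data.dropna(subset=["exposed", "anestrus"]).copy()
    data["exposed"] = data["exposed"].astype(float)
    if data["exposed"].nunique() < 2:
        raise ValueError("both exposure classes must be present")
    if int(data["anestrus"].sum()) < min_cases:
        raise ValueError(f"need >= {min_cases} anestrus cases, "
                         f"got {int(data['anestrus'].sum())}")

    arr, ok = _fit_and_standardize(data, adjust, parity_group, mode)

    lo = hi = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n_boot):
            boot = data.iloc[rng.integers(0, len(data), size=len(data))]
            if boot["exposed"].nunique() < 2 or boot["anestrus"].nunique() < 2:
                continue
            try:
                draws.append(_fit_and_standardize(boot, adjust, parity_group, mode)[0])
            except (ZeroDivisionError, np.linalg.LinAlgError):
                continue
        if len(draws) >= max(10, n_boot // 2):
            lo, hi = (float(x) for x in np.percentile(draws, [2.5, 97.5]))
        else:
            logger.warning("bootstrap degenerate: only %d/%d usable resamples",
                           len(draws), n_boot)

    return ArrEstimate(herd=herd, parity_group=parity_group, arr=arr,
                       ci_low=lo, ci_high=hi, mode=mode, n_used=len(data),
                       n_boot=n_boot, converged=ok,
                       message="" if ok else "fit flagged (separation or non-convergence)")


def afp_series(records: pd.DataFrame, summaries: pd.DataFrame,
               rule: ExposureRule = ExposureRule(), mode: str = "standardized",
               arr_scope: str = "stratum", n_boot: int = 0,
               seed: int = 0) -> pd.DataFrame:
    """Per-cohort AF_P time series for every herd × parity stratum.

    One row per included cohort with the cohort's anestrus rate and pd, the
    aRR (stratum-level by default; ``arr_scope="cohort"`` refits within each
    cohort, necessarily without year/season adjustment), the AF_P, and a
    ``flag`` column: empty, ``no_cases`` (AF_P undefined, no anestrus in the
    cohort), or ``negative_afp`` (protective estimate, reported unclipped).
    """
    if arr_scope not in ("stratum", "cohort"):
        raise ValueError(f"unknown arr_scope {arr_scope!r}")
    if "exposed" not in records.columns:
        rec = add_indicators(records, rule)
        for col in ("cohort_index", "cohort_start"):
            if col in records.columns:
                rec[col] = records[col].to_numpy()
    else:
        rec = records
    if arr_scope == "cohort":
        logger.warning("per-cohort aRR models cannot adjust for year/season "
                       "(constant within a 21-day cohort)")

    rows = []
    for (herd, pg), strat in summaries.groupby(["herd", "parity_group"], sort=True):
        if not strat["included"].any():
            logger.warning("stratum (%s, %s) has no included cohorts; skipped", herd, pg)
            continue
        arr_est = None
        if arr_scope == "stratum":
            arr_est = estimate_arr(rec, herd=herd, parity_group=pg, rule=rule,
                                   mode=mode, n_boot=n_boot, seed=seed)
        for _, row in strat[strat["included"]].iterrows():
            if arr_scope == "cohort":
                sub = rec[(rec["herd"] == herd) & (rec["parity_group"] == pg)
                          & (rec["cohort_index"] == row["cohort_index"])]
                try:
                    arr_est = estimate_arr(sub, rule=rule, mode=mode, adjust=(),
                                           n_boot=n_boot, seed=seed)
                except (ValueError, ZeroDivisionError) as exc:
                    rows.append(_afp_row(herd, pg, row, np.nan, np.nan,
                                         f"arr_failed: {exc}"))
                    continue
            if row["n_anestrus"] == 0:
                rows.append(_afp_row(herd, pg, row, arr_est.arr, np.nan, "no_cases"))
                continue
            value = afp(float(row["pd"]), arr_est.arr)
            rows.append(_afp_row(herd, pg, row, arr_est.arr, value,
                                 "negative_afp" if value < 0 else ""))
    return pd.DataFrame(rows)


def _afp_row(herd, pg, row, arr, value, flag) -> dict:
    return {
        "herd": herd, "parity_group": pg,
        "cohort_index": int(row["cohort_index"]), "date_start": row["date_start"],
        "anestrus_rate": float(row["anestrus_prop"]),
        "pd": float(row["pd"]) if not pd.isna(row["pd"]) else np.nan,
        "arr": float(arr), "afp": value, "flag": flag,
    }
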