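"""Cow-level risk models.

Fits, per herd × parity stratum, the logistic models relating body condition
at calving (BCS) and postpartum change (ΔBCS) to five binary outcomes, and
the linear model for first-test milk yield. Continuous predictors are
centered at their stratum means, so a logistic coefficient is the log-odds
change per unit increase over the stratum mean; year and season enter as
categoricals (earliest year and Summer as reference), and parity {2, 3, 4+}
is added for the multiparous stratum. Milk models additionally adjust for
days in milk (DIM) and DIM^2.

Also provides the closed-form 2x2 odds ratio used as the independent oracle
for one-binary-predictor logistic fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import norm

logger = logging.getLogger(__name__)

#: |log-odds coefficient| beyond which a logistic fit is flagged as separated.
SEPARATION_BOUND = 15.0

#: Minimum stratum size offered to any cow-level model.
MIN_STRATUM_N = 50


@dataclass
class ModelFit:
    """One fitted cow-level model.

    ``terms`` has one row per model term with columns ``coef``, ``se``,
    ``ci_low``, ``ci_high``, ``p`` and, for logistic fits, ``or_``,
    ``or_ci_low``, ``or_ci_high`` (exponentiated Wald bounds).
    """

    outcome: str
    herd: object
    parity_group: object
    kind: str  # "logistic" | "linear"
    terms: pd.DataFrame
    n_used: int
    n_dropped: int
    converged: bool
    log_likelihood: float
    message: str = ""


def odds_ratio_2x2(a: float, b: float, c: float, d: float,
                   zero_cell: str = "warn") -> float:
    """Cross-product odds ratio (a·d)/(b·c) of a 2x2 table.

    Cells: a = exposed cases, b = unexposed cases, c = exposed controls,
    d = unexposed controls. ``zero_cell`` chooses the degenerate-table policy:
    ``"warn"`` returns 0 or inf with a warning; ``"haldane"`` adds 0.5 to
    every cell first. A margin of zeros (e.g. no cases at all) is undefined
    and raises.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("2x2 cells must be nonnegative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ZeroDivisionError("2x2 table has an all-zero margin; OR undefined")
    if zero_cell == "haldane" and np.any(cells == 0):
        a, b, c, d = cells + 0.5
    elif np.any(cells == 0):
        warnings.warn("zero cell in 2x2 table; odds ratio is 0 or unbounded",
                      RuntimeWarning, stacklevel=2)
        if b * c == 0:
            return float("inf")
    return (a * d) / (b * c) if b * c > 0 else float("inf")


def or_wald_ci_2x2(a, b, c, d, alpha: float = 0.05,
                   zero_cell: str = "warn") -> tuple[float, float, float]:
    """Odds ratio with a Wald CI on the log scale (point, low, high).

    With any zero cell the Wald SE is undefined; under the ``"warn"`` policy
    the CI is reported as (0, inf), under ``"haldane"`` all cells get +0.5.
    """
    point = odds_ratio_2x2(a, b, c, d, zero_cell=zero_cell)
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells == 0):
        if zero_cell == "haldane":
            cells = cells + 0.5
        else:
            return point, 0.0, float("inf")
    z = norm.ppf(1 - alpha / 2)
    se = float(np.sqrt(np.sum(1.0 / cells)))
    log_or = float(np.log((cells[0] * cells[3]) / (cells[1] * cells[2])))
    return point, float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))


def _build_formula(data: pd.DataFrame, response: str, predictors: tuple[str, ...],
                   adjust: tuple[str, ...], parity_group) -> tuple[str, pd.DataFrame, list[str]]:
    """Assemble the model formula, dropping constant adjusters."""
    data = data.copy()
    if "delta_bcs" in predictors and "delta_bcs" not in data.columns:
        data["delta_bcs"] = data["bcs_release"] - data["bcs_calving"]
    rhs: list[str] = []
    dropped: list[str] = []
    for p in predictors:
        if p in ("bcs_calving", "delta_bcs"):
            cname = {"bcs_calving": "bcs_c", "delta_bcs": "dbcs_c"}[p]
            data[cname] = data[p] - data[p].mean()
            rhs.append(cname)
        else:
            rhs.append(p)
    if "year" in adjust:
        if data["year"].nunique() > 1:
            rhs.append(f"C(year, Treatment({int(data['year'].min())}))")
        else:
            dropped.append("year")
    if "season" in adjust:
        if data["season"].nunique() > 1:
            ref = "Summer" if (data["season"] == "Summer").any() else sorted(data["season"].unique())[0]
            rhs.append(f"C(season, Treatment('{ref}'))")
        else:
            dropped.append("season")
    if "parity" in adjust and parity_group == "cow":
        data["parity4"] = np.minimum(data["parity"].astype(int), 4)
        if data["parity4"].nunique() > 1:
            rhs.append("C(parity4, Treatment(2))")
        else:
            dropped.append("parity")
    if not rhs:
        rhs = ["1"]
    return f"{response} ~ {' + '.join(rhs)}", data, dropped


def _terms_frame(res, logistic: bool) -> pd.DataFrame:
    ci = res.conf_int()
    out = pd.DataFrame({
        "term": res.params.index,
        "coef": res.params.to_numpy(),
        "se": res.bse.to_numpy(),
        "ci_low": ci[0].to_numpy(),
        "ci_high": ci[1].to_numpy(),
        "p": res.pvalues.to_numpy(),
    })
    if logistic:
        out["or_"] = np.exp(out["coef"])
        out["or_ci_low"] = np.exp(out["ci_low"])
        out["or_ci_high"] = np.exp(out["ci_high"])
    return out.reset_index(drop=True)


def _fit_logit(formula: str, data: pd.DataFrame):
    """Newton ML fit with a BFGS fallback for quasi-separated designs.

    Sparse categorical cells can make the Newton Hessian singular even when
    the likelihood has a usable optimum; BFGS sidesteps the per-step
    inversion and its result still carries Wald covariances.
    """
    model = smf.logit(formula, data=data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return model.fit(disp=0, maxiter=100)
        except np.linalg.LinAlgError:
            return model.fit(disp=0, maxiter=500, method="bfgs")


def _subset_stratum(records: pd.DataFrame, herd, parity_group) -> pd.DataFrame:
    data = records
    if herd is not None:
        data = data[data["herd"] == herd]
    if parity_group is not None:
        data = data[data["parity_group"] == parity_group]
    return data


def fit_cow_logistic(records: pd.DataFrame, outcome: str, herd=None, parity_group=None,
                     predictors: tuple[str, ...] = ("bcs_calving", "delta_bcs"),
                     adjust: tuple[str, ...] = ("year", "season", "parity"),
                     min_n: int = MIN_STRATUM_N) -> ModelFit:
    """Maximum-likelihood logistic fit of one outcome in one stratum.

    Continuous BCS/ΔBCS predictors are centered at their stratum means before
    fitting; Wald 95% CIs are computed on the log-odds scale and
    exponentiated in ``terms``. Records missing any model variable are
    dropped complete-case (count logged in ``n_dropped``). Raises when the
    stratum is too small or the outcome has a single class; separation
    (|coef| > 15) or non-convergence is returned flagged, never silently.
    """
    data = _subset_stratum(records, herd, parity_group)
    needed = [outcome, *predictors] + [c for c in ("year", "season", "parity") if c in adjust]
    needed = [c for c in dict.fromkeys(needed) if c in data.columns]
    n_offered = len(data)
    data = data.dropna(subset=needed)
    n_dropped = n_offered - len(data)
    if n_dropped:
        logger.info("fit_cow_logistic(%s): dropped %d incomplete records", outcome, n_dropped)
    if len(data) < min_n:
        raise ValueError(f"stratum has {len(data)} usable records; need >= {min_n}")
    if data[outcome].nunique() < 2:
        raise ValueError(f"outcome {outcome!r} has a single class in this stratum")

    formula, data, dropped_adj = _build_formula(data, outcome, predictors, adjust, parity_group)
    res = _fit_logit(formula, data)
    converged = bool(res.mle_retvals.get("converged", False))
    separated = bool(np.any(np.abs(res.params.to_numpy()) > SEPARATION_BOUND))
    msg = "; ".join(filter(None, [
        f"dropped constant adjusters: {dropped_adj}" if dropped_adj else "",
        "possible separation (|coef| > 15)" if separated else "",
        "did not converge" if not converged else "",
    ]))
    return ModelFit(outcome=outcome, herd=herd, parity_group=parity_group,
                    kind="logistic", terms=_terms_frame(res, logistic=True),
                    n_used=int(res.nobs), n_dropped=n_dropped,
                    converged=converged and not separated,
                    log_likelihood=float(res.llf), message=msg)


def fit_milk_linear(records: pd.DataFrame, herd=None, parity_group=None,
                    predictors: tuple[str, ...] = ("bcs_calving", "delta_bcs"),
                    adjust: tuple[str, ...] = ("year", "season", "parity"),
                    min_n: int = MIN_STRATUM_N) -> ModelFit:
    """OLS fit of first-test milk yield in one stratum.

    Regresses ``milk_kg`` on centered BCS, centered ΔBCS, year, season
    (parity for the multiparous stratum), DIM and DIM^2. Rank deficiency is
    flagged with the aliased terms named in ``message``.
    """
    data = _subset_stratum(records, herd, parity_group)
    needed = ["milk_kg", "milk_dim", *predictors] + \
        [c for c in ("year", "season", "parity") if c in adjust]
    needed = [c for c in dict.fromkeys(needed) if c in data.columns]
    n_offered = len(data)
    data = data.dropna(subset=needed)
    n_dropped = n_offered - len(data)
    if len(data) < min_n:
        raise ValueError(f"stratum has {len(data)} usable records; need >= {min_n}")

    formula, data, dropped_adj = _build_formula(data, "milk_kg", predictors, adjust, parity_group)
    data["dim"] = data["milk_dim"].astype(float)
    data["dim2"] = data["dim"] ** 2
    formula += " + dim + dim2"
    res = smf.ols(formula, data=data).fit()
    rank_deficient = res.df_model + 1 < len(res.params)
    aliased = [t for t, b in zip(res.params.index, np.isnan(res.bse)) if b]
    msg = "; ".join(filter(None, [
        f"dropped constant adjusters: {dropped_adj}" if dropped_adj else "",
        f"rank deficient; aliased terms: {aliased}" if rank_deficient or aliased else "",
    ]))
    return ModelFit(outcome="milk_kg", herd=herd, parity_group=parity_group,
                    kind="linear", terms=_terms_frame(res, logistic=False),
                    n_used=int(res.nobs), n_dropped=n_dropped,
                    converged=not (rank_deficient or aliased),
                    log_likelihood=float(res.llf), message=msg)


def cow_model_report(records: pd.DataFrame,
                     outcomes: tuple[str, ...] = ("anestrus", "metritis", "mastitis",
                                                  "pre100", "ai80")) -> pd.DataFrame:
    """Per-stratum model summary: BCS/ΔBCS odds ratios and milk estimates.

    One row per herd × parity group × predictor × model, mirroring the
    classic layout of OR (95% CI) columns per outcome plus a milk
    estimate (SE) column.
    """
    rows = []
    strata = records[["herd", "parity_group"]].drop_duplicates().sort_values(
        ["herd", "parity_group"]).itertuples(index=False)
    for herd, pg in strata:
        for outcome in outcomes:
            try:
                fit = fit_cow_logistic(records, outcome, herd=herd, parity_group=pg)
            except ValueError as exc:
                logger.warning("skipping %s/%s/%s: %s", herd, pg, outcome, exc)
                continue
            for pred, cname in (("bcs_calving", "bcs_c"), ("delta_bcs", "dbcs_c")):
                t = fit.terms[fit.terms["term"] == cname]
                if t.empty:
                    continue
                t = t.iloc[0]
                rows.append({"herd": herd, "parity_group": pg, "model": outcome,
                             "predictor": pred, "estimate": t["or_"],
                             "ci_low": t["or_ci_low"], "ci_high": t["or_ci_high"],
                             "se": t["se"], "p": t["p"], "scale": "odds ratio",
                             "n_used": fit.n_used, "converged": fit.converged})
        try:
            mfit = fit_milk_linear(records, herd=herd, parity_group=pg)
        except ValueError as exc:
            logger.warning("skipping %s/%s/milk: %s", herd, pg, exc)
            continue
        for pred, cname in (("bcs_calving", "bcs_c"), ("delta_bcs", "dbcs_c")):
            t = mfit.terms[mfit.terms["term"] == cname]
            if t.empty:
                continue
            t = t.iloc[0]
            rows.append({"herd": herd, "parity_group": pg, "model": "milk_kg",
                         "predictor": pred, "estimate": t["coef"],
                         "ci_low": t["ci_low"], "ci_high": t["ci_high"],
                         "se": t["se"], "p": t["p"], "scale": "kg/d",
                         "n_used": mfit.n_used, "converged": mfit.converged})
    return pd.DataFrame(rows)
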