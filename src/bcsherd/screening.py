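"""Quartile-threshold screening of cohort exposure prevalence.

Each quartile of the cohort-level poor-BCS prevalence is offered, one at a
time, as a threshold dichotomizing the 21-day cohorts; the dichotomy's
ability to identify cohorts whose anestrus proportion is above the stratum
median is evaluated by odds ratio (with Wald CI), sensitivity, specificity
and AUC, and the threshold with the highest AUC is selected per stratum.

For a single binary predictor the c-statistic has the closed form
``(Se + Sp) / 2`` (ties counted as half); a pair-counting Mann-Whitney
implementation is provided as an independent cross-check.

Flag coding. A cohort is "flagged" when its exposure prevalence is strictly
above the threshold. Sensitivity and specificity describe the flag as a
detector of the high-anestrus class (Se = P(flagged | high anestrus)). The
odds ratio is reported under the *protective* coding by default — the odds of
high anestrus for cohorts at/below the threshold (many cows in proper
condition) versus above — yielding ORs below 1 when poor condition raises
anestrus; ``coding="risk"`` reports the reciprocal. AUC is identical under
either coding, and the four cells are always carried so any convention can be
audited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohorts import cohort_quartiles, median_split
from .models import or_wald_ci_2x2

QUARTILE_LABELS = ("Q25", "Q50", "Q75")


@dataclass
class ThresholdEval:
    """Screening performance of one quartile threshold in one stratum.

    ``cells = (a, b, c, d)`` in the protective coding: a/b = high-anestrus
    cohorts at-or-below / above the threshold, c/d = low-anestrus cohorts
    at-or-below / above.
    """

    herd: object
    parity_group: object
    quartile_label: str
    threshold: float
    or_point: float
    or_ci_low: float
    or_ci_high: float
    sensitivity: float
    specificity: float
    auc: float
    n_cohorts: int
    cells: tuple[int, int, int, int]
    coding: str = "protective"


def c_statistic_binary(se: float, sp: float) -> float:
    """Exact c-statistic of a single binary predictor: (Se + Sp) / 2.

    Ties (case and control with the same predicted value) count as half a
    concordant pair, which is what collapses the two-point ROC curve's area
    to the mean of sensitivity and specificity.
    """
    if not (0 <= se <= 1 and 0 <= sp <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return (se + sp) / 2.0


def auc_pair_counting(scores, labels) -> float:
    """c-statistic by direct pair counting (Mann-Whitney U / (n1*n0)).

    Independent of :func:`c_statistic_binary`; counts, over all case-control
    pairs, the fraction where the case scores higher (ties as 1/2).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both label classes for an AUC")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def evaluate_threshold(summaries: pd.DataFrame, labels: pd.Series, threshold: float,
                       quartile_label: str = "", coding: str = "protective",
                       zero_cell: str = "warn") -> ThresholdEval:
    """Evaluate one exposure-prevalence threshold as a cohort-level alarm.

    ``summaries`` is one stratum's cohort table, ``labels`` the
    :func:`median_split` output on its included cohorts. A cohort is flagged
    iff ``exposure_prop > threshold`` (strict; a cohort exactly at the
    threshold is "below"). Raises if the labels have a single class.
    """
    if coding not in ("protective", "risk"):
        raise ValueError(f"unknown coding {coding!r}")
    inc = summaries[summaries["included"]]
    y = labels.reindex(inc.index).to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("median-split labels have a single class")
    flagged = (inc["exposure_prop"].to_numpy(dtype=float) > threshold)

    # protective coding: "exposure" = at/below the threshold
    a = int(np.sum(~flagged & (y == 1)))
    b = int(np.sum(flagged & (y == 1)))
    c = int(np.sum(~flagged & (y == 0)))
    d = int(np.sum(flagged & (y == 0)))

    se = b / (a + b)   # P(flagged | high anestrus)
    sp = c / (c + d)   # P(unflagged | low anestrus)
    auc = c_statistic_binary(se, sp)

    if coding == "protective":
        or_point, lo, hi = or_wald_ci_2x2(a, b, c, d, zero_cell=zero_cell)
        cells = (a, b, c, d)
    else:
        or_point, lo, hi = or_wald_ci_2x2(b, a, d, c, zero_cell=zero_cell)
        cells = (b, a, d, c)

    herd = inc["herd"].iloc[0] if "herd" in inc.columns else None
    pg = inc["parity_group"].iloc[0] if "parity_group" in inc.columns else None
    return ThresholdEval(herd=herd, parity_group=pg, quartile_label=quartile_label,
                         threshold=float(threshold), or_point=or_point,
                         or_ci_low=lo, or_ci_high=hi, sensitivity=se, specificity=sp,
                         auc=auc, n_cohorts=int(a + b + c + d), cells=cells,
                         coding=coding)


def screen_stratum(summaries: pd.DataFrame, quantile_method: str = "linear",
                   coding: str = "protective", zero_cell: str = "warn") -> list[ThresholdEval]:
    """Evaluate all three quartile thresholds for one stratum's cohort table."""
    qs = cohort_quartiles(summaries, method=quantile_method)
    labels = median_split(summaries)
    return [evaluate_threshold(summaries, labels, q, lab, coding=coding, zero_cell=zero_cell)
            for lab, q in zip(QUARTILE_LABELS, qs)]


def select_threshold(evals: list[ThresholdEval]) -> ThresholdEval:
    """Pick the evaluation with maximal AUC; ties go to the lower quartile."""
    if not evals:
        raise ValueError("no threshold evaluations to select from")
    order = {lab: i for i, lab in enumerate(QUARTILE_LABELS)}
    return max(evals, key=lambda e: (e.auc, -order.get(e.quartile_label, 0)))


def screening_report(evals: list[ThresholdEval]) -> pd.DataFrame:
    """Flat table of threshold evaluations (one row per stratum × quartile)."""
    return pd.DataFrame([{
        "herd": e.herd, "parity_group": e.parity_group,
        "quartile": e.quartile_label, "threshold_pct": 100 * e.threshold,
        "or": e.or_point, "or_ci_low": e.or_ci_low, "or_ci_high": e.or_ci_high,
        "se_pct": 100 * e.sensitivity, "sp_pct": 100 * e.specificity,
        "auc": e.auc, "n_cohorts": e.n_cohorts,
        "cell_a": e.cells[0], "cell_b": e.cells[1],
        "cell_c": e.cells[2], "cell_d": e.cells[3], "coding": e.coding,
    } for e in evals])
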