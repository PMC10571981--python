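"""Cow-level models: 2x2 oracle, logistic and linear fits, equivariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logit

from bcsherd import (fit_cow_logistic, fit_milk_linear, odds_ratio_2x2,
                     or_wald_ci_2x2)
from conftest import make_records

CELL = st.integers(min_value=1, max_value=30)


def records_from_2x2(a, b, c, d):
    """Expand a 2x2 table (exposed/unexposed x case/control) into cow rows."""
    x = np.repeat([1, 0, 1, 0], [a, b, c, d])
    y = np.repeat([1, 1, 0, 0], [a, b, c, d])
    rec = make_records(n=len(x), anestrus=0)
    rec["anestrus"] = y
    rec["xbin"] = x
    return rec


class TestOddsRatio2x2:
    @pytest.mark.parametrize("cells, expected", [
        ((10, 10, 10, 10), 1.0),
        ((4, 9, 22, 11), 44 / 198),    # realizes Se 9/13, Sp 22/33 -> OR 0.22
        ((5, 22, 9, 18), 90 / 198),    # realizes Se 22/27, Sp 9/27 -> OR 0.45
    ])
    def test_cross_product(self, cells, expected):
        assert odds_ratio_2x2(*cells) == pytest.approx(expected, rel=1e-12)

    def test_zero_cell_policies(self):
        with pytest.warns(RuntimeWarning):
            assert odds_ratio_2x2(5, 0, 3, 4) == np.inf
        with pytest.warns(RuntimeWarning):
            assert odds_ratio_2x2(0, 5, 3, 4) == 0.0
        # Haldane-Anscombe continuity correction
        assert odds_ratio_2x2(5, 0, 3, 4, zero_cell="haldane") == \
            pytest.approx((5.5 * 4.5) / (0.5 * 3.5))

    def test_zero_margin_undefined(self):
        with pytest.raises(ZeroDivisionError):
            odds_ratio_2x2(0, 0, 5, 5)

    def test_wald_ci_brackets_point(self):
        point, lo, hi = or_wald_ci_2x2(12, 7, 9, 20)
        assert lo < point < hi
        assert point == pytest.approx(odds_ratio_2x2(12, 7, 9, 20))


@settings(max_examples=25, deadline=None)
@given(a=CELL, b=CELL, c=CELL, d=CELL)
def test_logistic_single_predictor_matches_cross_product(a, b, c, d):
    """One-binary-predictor ML logistic fit reproduces the closed-form OR."""
    rec = records_from_2x2(a, b, c, d)
    fit = fit_cow_logistic(rec, "anestrus", predictors=("xbin",), adjust=(), min_n=4)
    est = float(fit.terms.set_index("term").loc["xbin", "or_"])
    assert est == pytest.approx(odds_ratio_2x2(a, b, c, d), abs=1e-6, rel=1e-6)


def test_intercept_only_recovers_logit_rate():
    rec = make_records(n=200, anestrus=0)
    rec.loc[: 49, "anestrus"] = 1  # rate 0.25
    fit = fit_cow_logistic(rec, "anestrus", predictors=(), adjust=())
    intercept = float(fit.terms["coef"].iloc[0])
    assert intercept == pytest.approx(logit(0.25), abs=1e-8)


def test_centering_changes_intercept_only():
    rng = np.random.default_rng(0)
    bcs = rng.choice([2.5, 2.75, 3.0, 3.25, 3.5], size=400)
    y = (rng.uniform(size=400) < 1 / (1 + np.exp(-(-1 + 0.8 * (bcs - 3))))).astype(int)
    rec = make_records(n=400, bcs=bcs, anestrus=y)
    fit1 = fit_cow_logistic(rec, "anestrus", predictors=("bcs_calving",), adjust=())
    rec2 = rec.assign(bcs_calving=rec["bcs_calving"] + 0.5,
                      bcs_release=rec["bcs_release"] + 0.5)
    fit2 = fit_cow_logistic(rec2, "anestrus", predictors=("bcs_calving",), adjust=())
    s1 = float(fit1.terms.set_index("term").loc["bcs_c", "coef"])
    s2 = float(fit2.terms.set_index("term").loc["bcs_c", "coef"])
    assert s1 == pytest.approx(s2, abs=1e-8)


def test_logistic_preconditions():
    small = make_records(n=30)
    with pytest.raises(ValueError, match=">= 50"):
        fit_cow_logistic(small, "anestrus")
    oneclass = make_records(n=100, anestrus=0)
    with pytest.raises(ValueError, match="single class"):
        fit_cow_logistic(oneclass, "anestrus", adjust=())


def test_separation_flagged_not_silent():
    rec = make_records(n=120, anestrus=0)
    rec["xbin"] = np.repeat([0, 1], 60)
    rec["anestrus"] = rec["xbin"]  # perfectly separated
    fit = fit_cow_logistic(rec, "anestrus", predictors=("xbin",), adjust=())
    assert not fit.converged
    assert "separation" in fit.message or "converge" in fit.message


def test_ci_width_shrinks_with_n():
    rng = np.random.default_rng(1)
    widths = []
    for n in (400, 6400):
        bcs = rng.choice([2.5, 3.0, 3.5], size=n)
        y = (rng.uniform(size=n) < 0.3).astype(int)
        rec = make_records(n=n, bcs=bcs, anestrus=y)
        fit = fit_cow_logistic(rec, "anestrus", predictors=("bcs_calving",), adjust=())
        t = fit.terms.set_index("term").loc["bcs_c"]
        widths.append(t["ci_high"] - t["ci_low"])
    assert widths[1] < widths[0]


class TestMilkLinear:
    def _milk_records(self, n, beta_bcs, resid_sd, seed=0):
        rng = np.random.default_rng(seed)
        bcs = rng.choice([2.5, 2.75, 3.0, 3.25, 3.5, 3.75], size=n)
        rel = bcs - rng.choice([0.0, 0.25, 0.5, 0.75], size=n)
        dim = rng.integers(30, 41, size=n)
        milk = (20 + beta_bcs * bcs - 1.5 * (rel - bcs) + 0.2 * dim - 0.002 * dim**2
                + rng.normal(0, resid_sd, size=n))
        rec = make_records(n=n, bcs=bcs, bcs_release=rel)
        rec["milk_kg"] = milk
        rec["milk_dim"] = dim
        return rec

    def test_recovers_known_slope(self):
        # generating slope mirrors a realistic 2.59 kg/d per BCS unit
        rec = self._milk_records(10_000, beta_bcs=2.59, resid_sd=5.0, seed=2)
        fit = fit_milk_linear(rec, adjust=())
        t = fit.terms.set_index("term").loc["bcs_c"]
        assert abs(t["coef"] - 2.59) < 3 * t["se"]

    def test_zero_noise_exact_interpolation(self):
        rec = self._milk_records(500, beta_bcs=1.7, resid_sd=1.0, seed=3)
        rng = np.random.default_rng(4)
        bcs = rec["bcs_calving"].to_numpy()
        dbcs = (rec["bcs_release"] - rec["bcs_calving"]).to_numpy()
        dim = rec["milk_dim"].to_numpy().astype(float)
        rec["milk_kg"] = 20 + 1.7 * bcs - 1.5 * dbcs + 0.2 * dim - 0.002 * dim**2
        fit = fit_milk_linear(rec, adjust=())
        t = fit.terms.set_index("term")
        assert float(t.loc["bcs_c", "coef"]) == pytest.approx(1.7, abs=1e-8)
        assert float(t.loc["dbcs_c", "coef"]) == pytest.approx(-1.5, abs=1e-8)

    def test_constant_shift_moves_intercept_only(self):
        rec = self._milk_records(800, beta_bcs=1.0, resid_sd=3.0, seed=5)
        f1 = fit_milk_linear(rec, adjust=())
        f2 = fit_milk_linear(rec.assign(milk_kg=rec["milk_kg"] + 7.0), adjust=())
        t1, t2 = f1.terms.set_index("term"), f2.terms.set_index("term")
        assert float(t2.loc["Intercept", "coef"] - t1.loc["Intercept", "coef"]) == \
            pytest.approx(7.0, abs=1e-8)
        assert float(t2.loc["bcs_c", "coef"]) == pytest.approx(
            float(t1.loc["bcs_c", "coef"]), abs=1e-8)
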