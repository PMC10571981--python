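"""21-day cohorts: binning, summaries, quartiles, median split."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from bcsherd import (assign_cohorts, cohort_quartiles, median_split,
                     summarize_cohorts)
from conftest import make_records


def records_at_offsets(offsets, start=date(2014, 1, 1), **kw):
    rec = make_records(n=len(offsets), **kw)
    rec["calving_date"] = [start + timedelta(days=int(o)) for o in offsets]
    return rec


class TestAssignCohorts:
    def test_half_open_bins(self):
        rec = records_at_offsets([0, 20, 21])
        out = assign_cohorts(rec, origin=date(2014, 1, 1))
        assert list(out["cohort_index"]) == [0, 0, 1]

    def test_four_year_window_gives_70_bins(self):
        rec = records_at_offsets([0, 1460])
        out = assign_cohorts(rec, origin=date(2014, 1, 1))
        assert out["cohort_index"].max() == 1460 // 21 == 69

    def test_origin_shift_translates_indices(self):
        offsets = np.arange(0, 200, 7)
        rec = records_at_offsets(offsets + 21)
        a = assign_cohorts(rec, origin=date(2014, 1, 1))
        b = assign_cohorts(rec, origin=date(2014, 1, 22))
        assert (a["cohort_index"] - b["cohort_index"] == 1).all()
        # within-cohort groupings intact
        assert a.groupby("cohort_index")["cow_id"].apply(tuple).tolist() == \
            b.groupby("cohort_index")["cow_id"].apply(tuple).tolist()

    def test_calving_before_origin_rejected(self):
        rec = records_at_offsets([0, 5])
        with pytest.raises(ValueError, match="precede"):
            assign_cohorts(rec, origin=date(2014, 1, 3))

    def test_default_origin_is_stratum_first_calving(self):
        rec = records_at_offsets([3, 10, 45])
        out = assign_cohorts(rec)
        assert list(out["cohort_index"]) == [0, 0, 2]
        assert out["cohort_start"].iloc[0] == date(2014, 1, 4)


class TestSummaries:
    def test_ratio_arithmetic(self):
        # 25 cows: 5 exposed, 4 anestrus of which 3 exposed
        rec = records_at_offsets(np.zeros(25), bcs=3.0, anestrus=0)
        rec.loc[:4, "bcs_calving"] = 2.5          # 5 exposed
        rec.loc[1:3, "anestrus"] = 1              # 3 exposed cases
        rec.loc[5, "anestrus"] = 1                # 1 unexposed case
        out = summarize_cohorts(assign_cohorts(rec))
        row = out.iloc[0]
        assert row["n"] == 25 and row["n_exposed"] == 5
        assert row["exposure_prop"] == pytest.approx(0.20)
        assert row["anestrus_prop"] == pytest.approx(0.16)
        assert row["pd"] == pytest.approx(0.75)

    def test_minimum_size_filter(self):
        rec = records_at_offsets(np.zeros(19))
        out = summarize_cohorts(assign_cohorts(rec))
        assert not out["included"].iloc[0]
        out20 = summarize_cohorts(assign_cohorts(records_at_offsets(np.zeros(20))))
        assert out20["included"].iloc[0]

    def test_conservation_and_tiling(self):
        rng = np.random.default_rng(0)
        rec = records_at_offsets(rng.integers(0, 400, size=500))
        out = summarize_cohorts(assign_cohorts(rec))
        assert out["n"].sum() == 500
        # date ranges are consecutive 21-day half-open intervals
        assert (out["cohort_index"].diff().dropna() == 1).all()
        assert all((pd.Timestamp(e) - pd.Timestamp(s)).days == 21
                   for s, e in zip(out["date_start"], out["date_end"]))
        assert list(out["date_start"][1:]) == list(out["date_end"][:-1])

    def test_pd_times_cases_is_exposed_cases(self):
        rng = np.random.default_rng(1)
        rec = records_at_offsets(rng.integers(0, 300, size=600),
                                 bcs=rng.choice([2.5, 3.0, 3.5], size=600),
                                 anestrus=rng.integers(0, 2, size=600))
        out = summarize_cohorts(assign_cohorts(rec))
        has = out["n_anestrus"] > 0
        np.testing.assert_allclose(out.loc[has, "pd"] * out.loc[has, "n_anestrus"],
                                   out.loc[has, "n_anestrus_exposed"], atol=1e-12)

    def test_empty_input_warns(self):
        rec = records_at_offsets([0]).iloc[:0]
        rec["cohort_index"] = []
        with pytest.warns(RuntimeWarning):
            out = summarize_cohorts(rec)
        assert out.empty


class TestQuartiles:
    def _summaries(self, props):
        return pd.DataFrame({"herd": "A", "parity_group": "heifer",
                             "exposure_prop": props, "included": True})

    def test_linear_interpolation(self):
        q25, q50, q75 = cohort_quartiles(self._summaries([0.1, 0.2, 0.3, 0.4]))
        assert q50 == pytest.approx(0.25)
        assert q25 == pytest.approx(0.175)
        assert q75 == pytest.approx(0.325)

    def test_degenerate_distribution(self):
        q = cohort_quartiles(self._summaries([0.3] * 6))
        assert q == (0.3, 0.3, 0.3)

    def test_permutation_invariance_and_order(self):
        rng = np.random.default_rng(2)
        props = rng.uniform(0, 1, size=11)
        a = cohort_quartiles(self._summaries(props))
        b = cohort_quartiles(self._summaries(rng.permutation(props)))
        assert a == b
        assert a[0] <= a[1] <= a[2]

    def test_too_few_cohorts_named_error(self):
        with pytest.raises(ValueError, match="stratum"):
            cohort_quartiles(self._summaries([0.1, 0.2, 0.3]))

    def test_alternative_method(self):
        q = cohort_quartiles(self._summaries([0.1, 0.2, 0.3, 0.4]),
                             method="inverted_cdf")
        assert q[1] in (0.2, 0.25)  # empirical-CDF convention, no interpolation
        assert q[1] == 0.2


class TestMedianSplit:
    def _summaries(self, props):
        return pd.DataFrame({"anestrus_prop": props, "included": True})

    def test_strictly_above(self):
        labels = median_split(self._summaries([0.1, 0.2, 0.3]))
        assert list(labels) == [0, 0, 1]

    def test_all_equal_all_zero(self):
        assert list(median_split(self._summaries([0.2] * 5))) == [0] * 5

    def test_even_n_interpolated_median(self):
        labels = median_split(self._summaries([0.1, 0.2, 0.3, 0.4]))
        assert list(labels) == [0, 0, 1, 1]

    def test_excluded_cohorts_ignored(self):
        s = pd.DataFrame({"anestrus_prop": [0.1, 0.2, 0.9, 0.9],
                          "included": [True, True, False, False]})
        labels = median_split(s)
        assert len(labels) == 2 and list(labels) == [0, 1]
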