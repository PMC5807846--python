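"""Counting-method rules: dedup, window, vital status, enumeration oracle."""

import numpy as np
import pandas as pd
import pytest

from prevalkit import count_limited_prevalence, limited_totals, person_level_dedup
from prevalkit.limited_prevalence import AGE_GROUPS, DURATION_BINS

from conftest import brute_force_limited, cells_to_dict, random_toy_records


def _rec(pid, dx, *, seq=1, ct="alpha", status="alive", exit="2013-12-31",
         birth="1950-07-01", sex="male"):
    return {
        "person_id": pid,
        "sex": sex,
        "birth_date": pd.Timestamp(birth),
        "diagnosis_date": pd.Timestamp(dx),
        "cancer_type": ct,
        "sequence_number": seq,
        "vital_status": status,
        "exit_date": pd.Timestamp(exit),
    }


class TestDedup:
    def test_keeps_lowest_sequence(self):
        df = pd.DataFrame([_rec(1, "2001-01-01", seq=1, ct="beta"),
                           _rec(1, "2003-01-01", seq=2, ct="alpha")])
        out = person_level_dedup(df)
        assert len(out) == 1 and out.iloc[0]["cancer_type"] == "beta"

    def test_single_primary_identity(self):
        df = pd.DataFrame([_rec(1, "2001-01-01"), _rec(2, "2002-01-01")])
        pd.testing.assert_frame_equal(person_level_dedup(df), df)

    def test_same_day_tie_breaks_by_type_code(self):
        # two same-day primaries with equal sequence is invalid input; with
        # distinct sequences but equal dates, the lower sequence wins; with
        # equal sequence numbers the call must fail loudly
        df = pd.DataFrame([_rec(1, "2001-05-05", seq=1, ct="zeta"),
                           _rec(1, "2001-05-05", seq=1, ct="alpha")])
        with pytest.raises(ValueError, match="duplicate"):
            person_level_dedup(df)

    def test_deterministic_tie_break_on_dates_and_type(self):
        df = pd.DataFrame([_rec(1, "2001-05-05", seq=2, ct="zeta"),
                           _rec(1, "2001-05-05", seq=2, ct="alpha")])
        df.loc[1, "sequence_number"] = 3  # distinct (person, seq) pairs
        out1 = person_level_dedup(df)
        out2 = person_level_dedup(df.iloc[::-1].reset_index(drop=True))
        assert out1.iloc[0]["cancer_type"] == out2.iloc[0]["cancer_type"] == "zeta"


class TestCountingRules:
    INDEX = "2010-01-01"

    def test_alive_within_window_counted(self):
        df = pd.DataFrame([_rec(1, "2005-06-01")])
        cells = count_limited_prevalence(df, self.INDEX, 5, age_groups=None, duration_bins=None)
        assert cells["count"].sum() == 2  # 'all' + per-type strata

    def test_dead_before_index_not_counted(self):
        df = pd.DataFrame([_rec(1, "2002-01-01", status="dead", exit="2008-03-01")])
        cells = count_limited_prevalence(df, self.INDEX, 34)
        assert cells.empty

    def test_death_before_diagnosis_is_hard_error(self):
        df = pd.DataFrame([_rec(1, "2005-01-01", status="dead", exit="2004-01-01")])
        with pytest.raises(ValueError, match="death before diagnosis"):
            count_limited_prevalence(df, self.INDEX, 10)

    def test_diagnosis_after_index_excluded_with_log(self, caplog):
        df = pd.DataFrame([_rec(1, "2011-01-01"), _rec(2, "2005-01-01")])
        with caplog.at_level("WARNING"):
            cells = count_limited_prevalence(df, self.INDEX, 10, age_groups=None,
                                             duration_bins=None)
        assert "excluded 1" in caplog.text
        assert cells.loc[cells["cancer_type"] == "all", "count"].sum() == 1

    def test_lost_counted_as_alive_by_default_with_switch(self):
        df = pd.DataFrame([_rec(1, "2005-01-01", status="lost", exit="2007-01-01")])
        inc = count_limited_prevalence(df, self.INDEX, 10)
        exc = count_limited_prevalence(df, self.INDEX, 10, count_lost_as_alive=False)
        assert inc["count"].sum() == 2 and exc.empty

    def test_duration_floored_from_exact_days(self):
        # diagnosed 2005-01-02: 1825 days before 2010-01-01 -> floor 4 years
        df = pd.DataFrame([_rec(1, "2005-01-02")])
        cells = count_limited_prevalence(df, self.INDEX, 34, age_groups=None,
                                         duration_bins=None)
        assert set(cells["duration"]) == {4}


class TestEnumerationOracle:
    def test_counts_equal_brute_force_on_randomised_registries(self):
        """Counting-method output equals record-by-record enumeration."""
        for seed in range(12):
            rng = np.random.default_rng(seed)
            rec = random_toy_records(rng, n_persons=120)
            for L in (5, 15):
                cells = count_limited_prevalence(
                    rec, "2010-01-01", L, age_groups=None, duration_bins=None
                )
                assert cells_to_dict(cells) == brute_force_limited(rec, "2010-01-01", L)

    def test_monotone_in_window_length(self):
        rng = np.random.default_rng(99)
        rec = random_toy_records(rng, n_persons=300)
        c5 = limited_totals(count_limited_prevalence(rec, "2010-01-01", 5, age_groups=None))
        c15 = limited_totals(count_limited_prevalence(rec, "2010-01-01", 15, age_groups=None))
        merged = c5.merge(c15, on=["cancer_type", "sex", "age"], how="left",
                          suffixes=("_5", "_15"))
        assert (merged["N_L_5"] <= merged["N_L_15"].fillna(0) + 1e-9).all()

    def test_duration_bins_partition_and_sum_to_totals(self):
        rng = np.random.default_rng(4)
        rec = random_toy_records(rng, n_persons=300)
        binned = count_limited_prevalence(rec, "2010-01-01", 15)
        yearly = count_limited_prevalence(rec, "2010-01-01", 15, duration_bins=None)
        a = limited_totals(binned).set_index(["cancer_type", "sex", "age_group"])["N_L"]
        b = limited_totals(yearly).set_index(["cancer_type", "sex", "age_group"])["N_L"]
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())

    def test_all_types_not_more_than_per_type_sum(self):
        rng = np.random.default_rng(17)
        rec = random_toy_records(rng, n_persons=400)
        cells = count_limited_prevalence(rec, "2010-01-01", 20)
        total = cells.groupby("cancer_type", observed=True)["count"].sum()
        assert total["all"] <= total.drop("all").sum()
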