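"""Estimation arithmetic: N = N_L / R, duration splits, national scaling."""

import numpy as np
import pandas as pd
import pytest

from prevalkit import (
    COMPLETE,
    CureParams,
    CureParamSet,
    IncidenceModel,
    add_proportions,
    complete_prevalence,
    duration_split,
    national_totals,
    scale_to_national,
)
from prevalkit.cure_survival import AGE_CLASSES


def _cells(n=800, ct="alpha", sex="male", age_group="55-64"):
    return pd.DataFrame(
        {"cancer_type": [ct], "sex": [sex], "age_group": [age_group],
         "duration_bin": ["0-1"], "count": [n]}
    )


def _r_table(R, ct="alpha", sex="male", age_group="55-64"):
    return pd.DataFrame(
        {"cancer_type": [ct], "sex": [sex], "age_group": [age_group], "R": [R]}
    )


class TestCompletePrevalence:
    def test_hand_arithmetic(self):
        out = complete_prevalence(_cells(800), _r_table(0.8))
        assert out.loc[0, "N"] == pytest.approx(1000.0)
        assert out.loc[0, "se"] == pytest.approx(np.sqrt(800) / 0.8)

    def test_unit_index_is_identity(self):
        out = complete_prevalence(_cells(437), _r_table(1.0))
        assert out.loc[0, "N"] == 437.0

    def test_missing_index_cell_is_error(self):
        with pytest.raises(ValueError, match="no completeness index"):
            complete_prevalence(_cells(), _r_table(0.8, age_group="65-74"))

    def test_multi_cell_merge_keeps_every_cell(self):
        cells = pd.concat(
            [_cells(100, age_group="45-54"), _cells(200, age_group="55-64")],
            ignore_index=True,
        )
        r = pd.concat(
            [_r_table(0.5, age_group="45-54"), _r_table(0.8, age_group="55-64")],
            ignore_index=True,
        )
        out = complete_prevalence(cells, r).set_index("age_group")
        assert out.loc["45-54", "N"] == pytest.approx(200.0)
        assert out.loc["55-64", "N"] == pytest.approx(250.0)


def _flat_models():
    """Constant incidence, cure everyone: beyond-window mass is uniform in t."""
    inc = IncidenceModel.from_loglinear(
        rate_at_ref=1e-3, age_slope=0.0, cohort_slope=0.0,
        cohort_range=(1880.0, 2015.0),
    )
    cure = CureParamSet(
        [CureParams(pi=1.0, lam=2.0, gamma=1.0, stratum=("alpha", s, lbl))
         for s in ("male", "female") for _, _, lbl in AGE_CLASSES]
    )
    return {"alpha": {"male": inc}}, cure


class TestDurationSplit:
    def _inputs(self, n_l=800.0, n=1000.0, age=30):
        by_year = pd.DataFrame(
            {"cancer_type": "alpha", "sex": "male", "age": age,
             "duration": np.arange(10), "count": n_l / 10}
        )
        complete = pd.DataFrame(
            [{"cancer_type": "alpha", "sex": "male", "age": age,
              "N_L": n_l, "N": n}]
        )
        return by_year, complete

    def test_uniform_surplus_split_hand_values(self, zero_mortality_table):
        by_year, complete = self._inputs()
        inc, cure = _flat_models()
        out = duration_split(
            by_year, complete, inc, cure, zero_mortality_table,
            window_L=10, index_year=2010,
        ).set_index("duration_bin")["count"]
        # observed bins keep their counts: 2x80, 3x80, 5x80
        assert out["[0,2)"] == pytest.approx(160.0)
        assert out["[2,5)"] == pytest.approx(240.0)
        assert out["[5,10)"] == pytest.approx(400.0)
        # surplus 200 uniform over t = 10..29: 5, 5 and 10 years
        assert out["[10,15)"] == pytest.approx(50.0)
        assert out["[15,20)"] == pytest.approx(50.0)
        assert out[">=20"] == pytest.approx(100.0)
        assert out[COMPLETE] == pytest.approx(1000.0)

    def test_bins_sum_exactly_to_complete_total(self, zero_mortality_table):
        by_year, complete = self._inputs(n_l=777.0, n=923.5, age=62)
        inc, cure = _flat_models()
        out = duration_split(
            by_year, complete, inc, cure, zero_mortality_table,
            window_L=10, index_year=2010,
        )
        bins = out[out["duration_bin"] != COMPLETE]["count"].sum()
        total = out.loc[out["duration_bin"] == COMPLETE, "count"].iloc[0]
        assert bins == pytest.approx(total)
        assert total == pytest.approx(923.5)

    def test_negative_surplus_clamped_with_warning(self, zero_mortality_table, caplog):
        by_year, complete = self._inputs(n_l=800.0, n=790.0)
        inc, cure = _flat_models()
        with caplog.at_level("WARNING"):
            out = duration_split(
                by_year, complete, inc, cure, zero_mortality_table,
                window_L=10, index_year=2010,
            )
        assert "clamping" in caplog.text
        beyond = out[out["duration_bin"].isin(["[10,15)", "[15,20)", ">=20"])]["count"]
        assert (beyond == 0).all()

    def test_binned_input_rejected(self, zero_mortality_table):
        inc, cure = _flat_models()
        bad = _cells()
        with pytest.raises(ValueError, match="single-year"):
            duration_split(bad, bad, inc, cure, zero_mortality_table,
                           window_L=10, index_year=2010)


class TestScaling:
    POP = pd.DataFrame(
        {"sex": ["male", "female"], "age_group": ["55-64", "55-64"],
         "population": [2_000_000.0, 2_500_000.0]}
    )

    def _props(self):
        table = pd.DataFrame(
            {"cancer_type": "alpha", "sex": ["male", "female"],
             "age_group": "55-64", "N": [500.0, 750.0]}
        )
        registry_pop = pd.DataFrame(
            {"sex": ["male", "female"], "age_group": "55-64",
             "population": [100_000.0, 150_000.0]}
        )
        return add_proportions(table, registry_pop, keys=("sex", "age_group"))

    def test_proportion_arithmetic(self):
        props = self._props()
        # 500 / 100k and 750 / 150k residents, per 100,000
        assert props["proportion"].tolist() == pytest.approx([500.0, 500.0])

    def test_national_counts_hand_fixture(self):
        scaled = scale_to_national(self._props(), self.POP)
        assert scaled["count"].tolist() == pytest.approx([10_000.0, 12_500.0])
        tot = national_totals(scaled)
        assert tot.loc[0, "count"] == pytest.approx(22_500.0)

    def test_scaling_is_linear_in_population(self):
        doubled = self.POP.assign(population=self.POP["population"] * 2)
        a = scale_to_national(self._props(), self.POP)["count"]
        b = scale_to_national(self._props(), doubled)["count"]
        assert b.tolist() == pytest.approx((2 * a).tolist())

    def test_missing_population_cell_is_error(self):
        with pytest.raises(ValueError, match="missing national population"):
            scale_to_national(self._props(), self.POP.iloc[:1])

    def test_missing_registry_population_is_error(self):
        table = pd.DataFrame(
            {"cancer_type": ["alpha"], "sex": ["male"], "age_group": ["55-64"],
             "N": [500.0]}
        )
        with pytest.raises(ValueError, match="missing population"):
            add_proportions(table, self.POP.iloc[1:], keys=("sex", "age_group"))
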