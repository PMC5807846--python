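"""Mixture cure model: closed forms, likelihood contracts, parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prevalkit import (
    CureParams,
    fit_cure_model,
    observed_survival,
    relative_survival,
    simulate_cure_cohort,
)
from prevalkit.cure_survival import age_class, mle_loglik

TRUTH = CureParams(pi=0.4, lam=2.0, gamma=1.2, stratum=("alpha", "male", "55-64"))


class TestRelativeSurvival:
    def test_starts_at_one_and_tends_to_cure_fraction(self):
        p = CureParams(pi=0.4, lam=2.0, gamma=1.3)
        assert relative_survival(p, 0.0) == 1.0
        assert relative_survival(p, 1e6) == pytest.approx(0.4, abs=1e-9)

    def test_closed_form_value(self):
        # pi + (1-pi) e^{-(t/lam)^gamma}: exponential case evaluated by hand
        p = CureParams(pi=0.4, lam=2.0, gamma=1.0)
        assert relative_survival(p, 2.0) == pytest.approx(0.4 + 0.6 * np.exp(-1.0))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            relative_survival(TRUTH, -0.1)

    @settings(max_examples=60, deadline=None)
    @given(
        pi=st.floats(0.0, 1.0),
        lam=st.floats(0.1, 20.0),
        gamma=st.floats(0.2, 4.0),
        t=st.floats(0.0, 60.0),
        dt=st.floats(0.01, 10.0),
        beta_p=st.floats(-1.0, 1.0),
    )
    def test_monotone_and_bounded(self, pi, lam, gamma, t, dt, beta_p):
        p = CureParams(pi=pi, lam=lam, gamma=gamma, beta_period=1.0)
        rs_t = relative_survival(p, t, beta_p)
        assert pi - 1e-12 <= rs_t <= 1.0 + 1e-12
        assert relative_survival(p, t + dt, beta_p) <= rs_t + 1e-12

    def test_worse_period_hazard_lowers_survival_pointwise(self):
        p = CureParams(pi=0.3, lam=2.0, gamma=1.1, beta_period=0.5)
        t = np.linspace(0.1, 30, 50)
        assert np.all(relative_survival(p, t, period=1.0) < relative_survival(p, t, period=0.0))


class TestObservedSurvival:
    def test_cure_everyone_equals_expected_survival(self, constant_q_table):
        p = CureParams(pi=1.0, lam=2.0, gamma=1.0)
        got = observed_survival(p, constant_q_table, "male", 60, 2000, 3.0)
        assert got == pytest.approx(0.9**3)

    def test_zero_background_equals_relative_survival(self, zero_mortality_table):
        p = CureParams(pi=0.4, lam=2.0, gamma=1.2)
        t = 4.5
        got = observed_survival(p, zero_mortality_table, "female", 50, 1995, t)
        assert got == pytest.approx(float(relative_survival(p, t)))

    def test_product_structure_hand_value(self, constant_q_table):
        p = CureParams(pi=0.4, lam=2.0, gamma=1.0)
        got = observed_survival(p, constant_q_table, "male", 70, 2001, 2.0)
        assert got == pytest.approx(0.9**2 * (0.4 + 0.6 * np.exp(-1.0)))


class TestFitting:
    def test_parameter_recovery_large_sample(self, life_table):
        data = simulate_cure_cohort(
            TRUTH, life_table, 20_000, sex="male", age_at_dx=60, dx_year=2000,
            followup_years=10, rng=np.random.default_rng(42),
        )
        fit = fit_cure_model(data, life_table, stratum=TRUTH.stratum)
        assert fit.converged
        assert fit.params.pi == pytest.approx(TRUTH.pi, abs=0.02)
        assert fit.params.lam == pytest.approx(TRUTH.lam, rel=0.1)
        assert fit.params.gamma == pytest.approx(TRUTH.gamma, rel=0.1)
        assert fit.se["pi"] < 0.02

    def test_loglik_at_fit_dominates_truth(self, life_table):
        data = simulate_cure_cohort(
            TRUTH, life_table, 3_000, sex="male", age_at_dx=60, dx_year=2000,
            followup_years=10, rng=np.random.default_rng(5),
        )
        fit = fit_cure_model(data, life_table, stratum=TRUTH.stratum)
        assert fit.loglik >= mle_loglik(TRUTH, data, life_table) - 1e-6

    def test_no_deaths_pins_cure_fraction_at_boundary(self, zero_mortality_table):
        p = CureParams(pi=1.0, lam=2.0, gamma=1.0)
        data = simulate_cure_cohort(
            p, zero_mortality_table, 500, followup_years=8,
            rng=np.random.default_rng(0),
        )
        assert not data["event"].any()
        fit = fit_cure_model(data, zero_mortality_table, min_events=0)
        assert fit.params.pi > 0.99
        assert any("boundary" in w for w in fit.warnings)

    def test_constant_period_column_flags_beta(self, life_table):
        data = simulate_cure_cohort(
            TRUTH, life_table, 4_000, dx_year=2000, followup_years=10,
            rng=np.random.default_rng(3),
        )
        fit = fit_cure_model(data, life_table, period_ref=2000)
        assert fit.params.beta_period == 0.0
        assert any("not identifiable" in w for w in fit.warnings)

    def test_period_effect_recovered_when_identifiable(self, life_table):
        rng = np.random.default_rng(8)
        truth = CureParams(pi=0.4, lam=2.0, gamma=1.2, beta_period=-0.03)
        dx_years = rng.integers(1990, 2010, size=20_000)
        data = simulate_cure_cohort(
            truth, life_table, 20_000, dx_year=dx_years, followup_years=10,
            period_ref=2000, rng=rng,
        )
        fit = fit_cure_model(data, life_table, period_ref=2000)
        assert fit.params.beta_period == pytest.approx(-0.03, abs=0.01)

    def test_too_few_events_is_an_error(self, life_table):
        data = simulate_cure_cohort(
            TRUTH, life_table, 30, followup_years=5, rng=np.random.default_rng(1)
        )
        with pytest.raises(ValueError, match="events"):
            fit_cure_model(data, life_table, min_events=1000)

    def test_ls_mode_agrees_with_mle_on_large_sample(self, life_table):
        data = simulate_cure_cohort(
            TRUTH, life_table, 30_000, followup_years=12, dx_year=1998,
            rng=np.random.default_rng(77),
        )
        mle = fit_cure_model(data, life_table)
        ls = fit_cure_model(data, life_table, method="ls")
        assert ls.params.pi == pytest.approx(mle.params.pi, abs=0.03)
        assert ls.params.lam == pytest.approx(mle.params.lam, rel=0.2)


def test_age_class_boundaries():
    assert age_class(14) == "0-14"
    assert age_class(15) == "15-44"
    assert list(age_class([44, 45, 74, 75, 99])) == ["15-44", "45-54", "65-74", "75+", "75+"]
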