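"""Structural model: covariates, flip-flop construction, closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedpk.model import (
    Covariates,
    DoseEvent,
    PopulationParameters,
    conc_history,
    conc_single_dose,
    conc_steady_state,
    exposure_metrics_ss,
    individual_params,
    typical_params,
)

from conftest import make_ind


def pop_with(**kw):
    base = dict(
        tvcl=1.0, cl_age=0.0, cl_sex=0.0, tvv=10.0, v_age=0.0, tvka=0.5,
        omega2_cl=0.0, omega2_v=0.0, sigma2_prop=0.0,
    )
    base.update(kw)
    return PopulationParameters(**base)


class TestCovariateModel:
    def test_covariates_switched_off_return_typical_values(self):
        pop = pop_with(tvcl=2.0, tvv=25.0, tvka=0.8)
        cov = Covariates(age=9.0, sex="female")
        assert typical_params(pop, cov) == (2.0, 25.0, 0.8)

    def test_centering_identity_at_reference_age_male(self):
        pop = pop_with(cl_age=0.1, cl_sex=-0.1, v_age=0.02, age_ref=5.0)
        cov = Covariates(age=5.0, sex="male")
        assert typical_params(pop, cov) == (1.0, 10.0, 0.5)

    def test_linear_age_scaling_hand_value(self):
        # 1 * (1 + 0.28 * 5) = 2.4 for a 5-year-old boy, slope 0.28/yr
        pop = pop_with(tvcl=1.0, cl_age=0.28)
        cov = Covariates(age=5.0, sex="male")
        tvcl_i, _, _ = typical_params(pop, cov)
        assert tvcl_i == pytest.approx(2.4, rel=1e-12)

    def test_sex_effect_applies_to_females_only(self):
        pop = pop_with(cl_sex=-0.08)
        boy, girl = Covariates(age=3, sex="male"), Covariates(age=3, sex="female")
        assert typical_params(pop, boy)[0] == 1.0
        assert typical_params(pop, girl)[0] == pytest.approx(0.92)

    def test_constructor_rejects_multiplier_negative_in_age_range(self):
        with pytest.raises(ValueError, match="multiplier"):
            pop_with(cl_age=-0.2)  # 1 - 0.2*14 < 0 at the top of the range

    @pytest.mark.parametrize("field,value", [
        ("tvcl", -1.0), ("tvv", 0.0), ("omega2_cl", -0.1), ("sigma2_prop", -1e-9),
    ])
    def test_constructor_rejects_invalid_scalars(self, field, value):
        with pytest.raises(ValueError):
            pop_with(**{field: value})


class TestIndividualParams:
    def test_zero_etas_reproduce_typical_values(self):
        pop = pop_with(cl_age=0.2, v_age=0.05)
        cov = Covariates(age=7.0, sex="male")
        ind = individual_params(pop, cov)
        tvcl_i, tvv_i, _ = typical_params(pop, cov)
        assert ind.cl == tvcl_i and ind.v == tvv_i

    def test_hand_arithmetic_rates_and_half_life(self):
        ind = make_ind(cl=3.0, v=30.0, tvka=0.5)
        assert ind.ke == pytest.approx(0.1)
        assert ind.ka == pytest.approx(0.6)
        assert ind.t_half == pytest.approx(6.93, abs=0.005)

    @given(
        eta_cl=st.floats(-2, 2), eta_v=st.floats(-2, 2),
        age=st.floats(0.5, 14), female=st.booleans(),
    )
    @settings(max_examples=60, deadline=None)
    def test_flipflop_gap_equals_tvka_exactly(self, eta_cl, eta_v, age, female):
        pop = pop_with(cl_age=0.25, cl_sex=-0.05, v_age=0.04, tvka=0.71)
        cov = Covariates(age=age, sex="female" if female else "male")
        ind = individual_params(pop, cov, eta_cl, eta_v)
        assert ind.ka - ind.ke == pytest.approx(0.71, rel=1e-12)
        assert ind.ka > ind.ke > 0


class TestSingleDose:
    def test_null_dose_and_time_zero(self):
        ind = make_ind()
        assert conc_single_dose(ind, 0.0, 5.0) == 0.0
        assert conc_single_dose(ind, 10.0, 0.0) == 0.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            conc_single_dose(make_ind(), 10.0, -0.5)

    def test_matches_ode_integration(self):
        """Closed form vs the two-ODE gut/central system (independent oracle)."""
        from scipy.integrate import solve_ivp

        ind = make_ind(cl=3.0, v=30.0, tvka=0.5)  # ke=0.1, ka=0.6
        dose = 10.0

        def rhs(t, y):
            a, c = y
            return [-ind.ka * a, ind.ka * a / ind.v - ind.ke * c]

        grid = np.linspace(0.25, 48, 40)
        sol = solve_ivp(rhs, (0, 48), [dose, 0.0], t_eval=grid,
                        rtol=1e-11, atol=1e-13, method="LSODA")
        ode = 1000.0 * sol.y[1]
        closed = conc_single_dose(ind, dose, grid)
        assert np.max(np.abs(closed - ode) / ode) < 1e-6

    @given(lam=st.floats(0.1, 10), t=st.floats(0.1, 72))
    @settings(max_examples=50, deadline=None)
    def test_dose_linearity(self, lam, t):
        ind = make_ind()
        c1 = conc_single_dose(ind, 10.0, t)
        assert conc_single_dose(ind, 10.0 * lam, t) == pytest.approx(lam * c1, rel=1e-12)

    def test_continuity_across_flipflop_degeneracy(self):
        """Closed and limit forms agree across the switching tolerance."""
        ke = 0.1
        t = np.linspace(0.5, 48, 30)
        vals = []
        for rel_gap in (2e-13, 5e-13, 2e-12, 5e-12):
            ind = make_ind(cl=ke * 30.0, v=30.0, tvka=ke * rel_gap)
            vals.append(conc_single_dose(ind, 10.0, t))
        for a, b in zip(vals, vals[1:]):
            assert np.max(np.abs(a - b) / np.abs(a)) < 1e-8


class TestDosingHistory:
    def test_single_dose_reduction(self):
        ind = make_ind()
        t = np.linspace(0, 24, 25)
        via_hist = conc_history(ind, [DoseEvent(0.0, 10.0)], t)
        direct = conc_single_dose(ind, 10.0, t)
        assert np.allclose(via_hist, direct, rtol=0, atol=0)

    def test_coincident_doses_add(self):
        ind = make_ind()
        two = conc_history(ind, [DoseEvent(0, 5.0), DoseEvent(0, 5.0)], 6.0)
        one = conc_history(ind, [DoseEvent(0, 10.0)], 6.0)
        assert two == pytest.approx(one, rel=1e-12)

    def test_unsorted_history_rejected(self):
        ind = make_ind()
        with pytest.raises(ValueError, match="sorted"):
            conc_history(ind, [DoseEvent(12, 5.0), DoseEvent(0, 5.0)], 13.0)

    def test_superposition_converges_to_steady_state(self):
        """200 q12h doses reproduce the closed-form steady state to 1e-6."""
        ind = make_ind(cl=3.0, v=30.0, tvka=0.5)
        tau, n = 12.0, 200
        doses = [DoseEvent(i * tau, 5.0) for i in range(n)]
        t_in = np.linspace(0.5, tau, 12)
        sup = conc_history(ind, doses, (n - 1) * tau + t_in)
        ss = conc_steady_state(ind, 5.0, tau, t_in)
        assert np.max(np.abs(sup - ss) / ss) < 1e-6


class TestSteadyState:
    def test_periodicity(self):
        ind = make_ind()
        assert conc_steady_state(ind, 5.0, 12.0, 0.0) == pytest.approx(
            conc_steady_state(ind, 5.0, 12.0, 12.0), rel=1e-12
        )

    def test_zero_dose(self):
        assert conc_steady_state(make_ind(), 0.0, 12.0, 5.0) == 0.0

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            conc_steady_state(make_ind(), 5.0, 0.0, 0.0)

    @given(t=st.floats(0.1, 11.9))
    @settings(max_examples=40, deadline=None)
    def test_accumulation_dominates_single_dose(self, t):
        ind = make_ind()
        assert conc_steady_state(ind, 5.0, 12.0, t) >= conc_single_dose(ind, 5.0, t)


class TestExposureMetrics:
    def test_max_min_ordering_and_mass_balance(self):
        ind = make_ind(cl=2.0, v=25.0, tvka=0.9)
        m = exposure_metrics_ss(ind, 5.0, 12.0)
        assert m.cmax_ss >= m.cmin_ss > 0
        assert m.auc_tau == pytest.approx(1000.0 * 5.0 / ind.cl, rel=1e-12)

    def test_against_dense_grid_search(self):
        """Analytic Tmax/Cmax/Cmin vs a 1e-4 h grid scan of the interval."""
        ind = make_ind(cl=3.0, v=30.0, tvka=0.5)
        dose, tau = 10.0, 24.0
        m = exposure_metrics_ss(ind, dose, tau)
        grid = np.arange(0.0, tau + 1e-9, 1e-4)
        c = conc_steady_state(ind, dose, tau, grid)
        i = int(np.argmax(c))
        assert m.cmax_ss == pytest.approx(float(c[i]), rel=1e-7)
        assert abs(m.tmax_ss - grid[i]) <= 1e-4
        assert m.cmin_ss == pytest.approx(float(c[-1]), rel=1e-9)

    def test_zero_dose_metrics(self):
        m = exposure_metrics_ss(make_ind(), 0.0, 12.0)
        assert (m.cmax_ss, m.cmin_ss, m.auc_tau) == (0.0, 0.0, 0.0)
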