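"""Closed-form estimator checks: unit conversions, Bernoulli variants,
the adjusted power law, Gorlin, Borda-Carnot, geometry and Reynolds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tpgmodel import (
    REFERENCE_COEFFICIENTS,
    FluidProperties,
    GorlinInputs,
    ModelCoefficients,
    ValveState,
    adjusted_model_tpg,
    adjusted_model_tpg_reduced,
    average_velocity,
    bernoulli_avg_tpg,
    bernoulli_coefficient,
    bernoulli_max_tpg,
    borda_carnot_loss,
    characteristic_diameter,
    gorlin_ava,
    gorlin_tpg,
    mean_to_peak_tpg,
    mmhg_from_pa,
    pa_from_mmhg,
    peak_to_mean_tpg,
    reynolds_number,
)

finite_pressures = st.floats(-1e6, 1e6, allow_nan=False)


class TestPressureConversion:
    @pytest.mark.parametrize(
        "pa, mmhg",
        [(133.32, 1.0), (0.0, 0.0), (8400.0, 63.0063)],
    )
    def test_known_values(self, pa, mmhg):
        assert mmhg_from_pa(pa) == pytest.approx(mmhg, abs=5e-4)

    @given(p=finite_pressures)
    @settings(max_examples=50, derandomize=True)
    def test_round_trip_exact(self, p):
        assert pa_from_mmhg(mmhg_from_pa(p)) == pytest.approx(p, rel=1e-15, abs=1e-12)


class TestVelocitiesAndBernoulli:
    @pytest.mark.parametrize(
        "ava, q, v",
        [(1.0, 0.1, 1.0), (2.0, 0.0, 0.0), (1.87, 0.318, 1.70053)],
    )
    def test_average_velocity(self, ava, q, v):
        assert average_velocity(ValveState(ava=ava, q=q)) == pytest.approx(v, abs=1e-5)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError, match="valve area"):
            ValveState(ava=-1.0, q=0.1)

    @pytest.mark.parametrize("v, tpg", [(4.0, 64.0), (0.0, 0.0), (2.0, 16.0)])
    def test_bernoulli_max(self, v, tpg):
        assert bernoulli_max_tpg(v) == tpg

    def test_bernoulli_max_rejects_negative_velocity(self):
        with pytest.raises(ValueError):
            bernoulli_max_tpg(-1.0)

    @given(v=st.floats(0, 20), lam=st.floats(0, 5))
    @settings(max_examples=50, derandomize=True)
    def test_bernoulli_max_quadratic_scaling(self, v, lam):
        assert bernoulli_max_tpg(lam * v) == pytest.approx(
            lam**2 * bernoulli_max_tpg(v), rel=1e-12, abs=1e-12
        )

    def test_dimensional_coefficient(self):
        assert bernoulli_coefficient() == pytest.approx(3.93789, abs=1e-5)
        assert bernoulli_coefficient(rounded=True) == 4.0
        assert bernoulli_coefficient(FluidProperties(rho=0.0)) == 0.0

    @pytest.mark.parametrize(
        "ava, q, tpg",
        [(1.0, 0.1, 4.0), (2.0, 0.0, 0.0), (1.87, 0.318, 11.567)],
    )
    def test_bernoulli_avg(self, ava, q, tpg):
        assert bernoulli_avg_tpg(ValveState(ava=ava, q=q)) == pytest.approx(tpg, abs=2e-3)

    def test_peak_velocity_estimate_dominates_average(self):
        # v_max >= area-averaged velocity is a type invariant, so the
        # peak-velocity Bernoulli estimate can never fall below the
        # average-velocity one
        state = ValveState(ava=1.5, q=0.3, v_max=2.6)
        assert bernoulli_max_tpg(state.v_max) >= bernoulli_avg_tpg(state)
        with pytest.raises(ValueError, match="below the area-averaged"):
            ValveState(ava=1.5, q=0.3, v_max=1.0)


class TestAdjustedModel:
    def test_reference_point(self):
        state = ValveState(ava=1.0, q=0.1)
        assert adjusted_model_tpg(state, REFERENCE_COEFFICIENTS) == pytest.approx(
            4.9446, abs=1e-3
        )

    def test_zero_flow_degenerate_limit(self):
        with pytest.warns(UserWarning, match="zero flow"):
            assert adjusted_model_tpg(ValveState(ava=2.0, q=0.0)) == 0.0

    def test_full_and_reduced_forms_agree(self, rng):
        # Eq. with explicit v^2 factor vs the reduced exponent-shifted form
        for _ in range(100):
            state = ValveState(
                ava=float(rng.uniform(0.5, 4.5)), q=float(rng.uniform(0.05, 1.0))
            )
            full = adjusted_model_tpg(state, REFERENCE_COEFFICIENTS)
            reduced = adjusted_model_tpg_reduced(state, REFERENCE_COEFFICIENTS)
            assert reduced == pytest.approx(full, rel=1e-10)

    def test_reduced_form_parameter_mapping(self):
        co = ModelCoefficients(c=3.007, alpha=-0.373, beta=-0.216)
        assert co.c_reduced == pytest.approx(300.7)
        assert co.alpha_reduced == pytest.approx(-2.373)
        assert co.beta_reduced == pytest.approx(1.784)
        back = ModelCoefficients.from_reduced(co.c_reduced, co.alpha_reduced, co.beta_reduced)
        assert (back.c, back.alpha, back.beta) == pytest.approx((co.c, co.alpha, co.beta))

    def test_ci_must_contain_point(self):
        with pytest.raises(ValueError, match="does not contain"):
            ModelCoefficients(c=3.0, alpha=-0.4, beta=-0.2, ci_c=(3.1, 3.2))


class TestGorlin:
    def test_worked_example(self):
        g = GorlinInputs(co=5000, hr=63, sep=0.33, tpg_mean=25)
        assert gorlin_ava(g) == pytest.approx(1.086, abs=1e-3)

    def test_round_trip(self):
        g = GorlinInputs(co=4800, hr=70, sep=0.31, tpg_mean=32.5)
        assert gorlin_tpg(g, gorlin_ava(g)) == pytest.approx(g.tpg_mean, rel=1e-12)

    def test_sqrt_gradient_dependence(self):
        g1 = GorlinInputs(co=5000, hr=63, sep=0.33, tpg_mean=25)
        g4 = GorlinInputs(co=5000, hr=63, sep=0.33, tpg_mean=100)
        assert gorlin_ava(g4) == pytest.approx(gorlin_ava(g1) / 2, rel=1e-12)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            GorlinInputs(co=5000, hr=63, sep=0.33, tpg_mean=0)


class TestBordaCarnot:
    def test_sudden_expansion_of_a_4ms_jet(self):
        assert borda_carnot_loss(4.0, 0.0, xi=1.0) == pytest.approx(63.006, abs=1e-3)
        assert borda_carnot_loss(4.0, 0.0, xi=1.0, as_pa=True) == pytest.approx(8400.0)

    def test_no_velocity_change_no_loss(self):
        assert borda_carnot_loss(2.5, 2.5, xi=0.7) == 0.0

    def test_symmetry(self):
        assert borda_carnot_loss(0.0, 4.0) == borda_carnot_loss(4.0, 0.0)

    @pytest.mark.parametrize("xi", [-0.1, 1.1])
    def test_loss_coefficient_bounds(self, xi):
        with pytest.raises(ValueError, match="loss coefficient"):
            borda_carnot_loss(4.0, 0.0, xi=xi)


class TestGeometryAndReynolds:
    def test_characteristic_diameter(self):
        assert characteristic_diameter(math.pi) == pytest.approx(2.0, rel=1e-12)
        assert characteristic_diameter(0.0) == 0.0
        assert characteristic_diameter(1.87) == pytest.approx(1.5430, abs=1e-4)
        with pytest.raises(ValueError):
            characteristic_diameter(-1.0)

    def test_reynolds_reference_point(self):
        # u = 1 m/s through a 2 cm orifice (area pi cm², q = pi/10 l/s)
        state = ValveState(ava=math.pi, q=math.pi / 10.0)
        assert reynolds_number(state) == pytest.approx(6000.0, rel=1e-9)

    def test_reynolds_cohort_mean_state(self):
        # hand value 1050 * 1.70053 * 0.0154303 / 0.0035; inside the
        # physiological orifice-Reynolds range 500-14000
        re = reynolds_number(ValveState(ava=1.87, q=0.318))
        assert re == pytest.approx(7872.0, abs=0.5)
        assert 500 < re < 14000

    def test_reynolds_zero_flow(self):
        assert reynolds_number(ValveState(ava=2.0, q=0.0)) == 0.0


class TestPeakMeanConversion:
    def test_division(self):
        assert peak_to_mean_tpg(64.0, 1.6) == pytest.approx(40.0)

    def test_identity_warns_outside_clinical_range(self):
        with pytest.warns(UserWarning, match="conventional clinical"):
            assert peak_to_mean_tpg(30.0, 1.0) == 30.0

    @given(x=st.floats(0, 300), a=st.floats(1.56, 1.68))
    @settings(max_examples=50, derandomize=True)
    def test_round_trip(self, x, a):
        assert mean_to_peak_tpg(peak_to_mean_tpg(x, a), a) == pytest.approx(
            x, rel=1e-15, abs=1e-12
        )

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            peak_to_mean_tpg(40.0, 0.0)
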