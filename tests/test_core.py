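"""Closed-form filtration physics: pressures, rate law, kinetics and the
steady-state volume/area relationship."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasmasep.core import (
    CakeProperties,
    DeviceGeometry,
    FiltrationModel,
    FluidProperties,
    capillary_pressure,
    d2Vq_dA2,
    dVq_dA,
    filtering_constant,
    filtration_rate,
    relative_rate_q,
    steady_state_time,
    steady_state_volume,
    volume_at_time,
)

from conftest import ode_volume

models = st.builds(
    FiltrationModel,
    k=st.floats(5e-3, 0.5),
    Ve=st.just(0.0) | st.floats(0.01, 20.0),
    q_th=st.just(0.05),
)
areas = st.floats(1.0, 50.0)


class TestCapillaryPressure:
    @pytest.mark.parametrize(
        "gamma, theta, h, expected",
        [
            (0.05, 0.0, 100.0, 1000.0),  # 2*0.05/1e-4
            (0.058, 27.0, 80.0, 2 * 0.058 * math.cos(math.radians(27)) / 8e-5),
        ],
    )
    def test_thin_slit_values(self, gamma, theta, h, expected):
        p = capillary_pressure(FluidProperties(gamma, theta, 1e-3), DeviceGeometry(h=h))
        assert p.delta_p == pytest.approx(expected, rel=1e-12)

    def test_ninety_degree_contact_angle_gives_zero(self):
        p = capillary_pressure(FluidProperties(0.07, 90.0, 1e-3), DeviceGeometry(h=80))
        assert p.delta_p == pytest.approx(0.0, abs=1e-10)

    def test_obtuse_angle_gives_negative_pressure(self):
        p = capillary_pressure(FluidProperties(0.07, 120.0, 1e-3), DeviceGeometry(h=80))
        assert p.delta_p < 0

    def test_thin_slit_is_wide_channel_limit(self):
        fluid = FluidProperties(0.058, 27.0, 1e-3)
        slit = capillary_pressure(fluid, DeviceGeometry(h=80.0)).delta_p
        wide = capillary_pressure(fluid, DeviceGeometry(h=80.0, w=80.0 * 1e7)).delta_p
        assert abs(wide - slit) / slit < 1e-6

    def test_nonpositive_height_rejected(self):
        with pytest.raises(ValueError):
            DeviceGeometry(h=0.0)


class TestFilteringConstant:
    def test_si_value_and_unit_conversion(self):
        # 2*1000/(1e12 * 1.5e-3 * 0.5) = 2.6667e-6 m^2/s; with
        # 1 uL^2 mm^-4 = 1e-6 m^2 and 60 s/min this is 160 canonical units
        k = filtering_constant(1000.0, CakeProperties(r=1e12, v=0.5), mu=1.5e-3)
        assert k == pytest.approx(2.6667e-6 * 60 / 1e-6, rel=1e-4)
        assert k == pytest.approx(160.0, rel=1e-4)

    def test_proportionalities(self):
        cake = CakeProperties(r=1e12, v=0.5)
        base = filtering_constant(1000.0, cake, mu=1.5e-3)
        assert filtering_constant(2000.0, cake, 1.5e-3) == pytest.approx(2 * base)
        half = filtering_constant(1000.0, CakeProperties(r=2e12, v=0.5), 1.5e-3)
        assert half == pytest.approx(base / 2)

    def test_zero_pressure_rejected(self):
        with pytest.raises(ValueError):
            filtering_constant(0.0, CakeProperties(r=1e12, v=0.5), mu=1.5e-3)
        with pytest.raises(ValueError):
            FiltrationModel(k=0.0)


class TestFiltrationRate:
    def test_hand_value(self, model):
        assert filtration_rate(model, A=5.0, V=3.0) == pytest.approx(0.25)

    def test_strictly_decreasing_in_volume(self, model):
        assert filtration_rate(model, 5.0, 10.0) < filtration_rate(model, 5.0, 1.0)

    def test_vanishes_at_large_volume(self, model):
        assert filtration_rate(model, 5.0, 1e9) < 1e-8

    def test_cake_free_start_is_domain_error(self):
        with pytest.raises(ValueError):
            filtration_rate(FiltrationModel(k=0.1, Ve=0.0), 5.0, 0.0)


class TestVolumeAtTime:
    def test_starts_at_zero(self, model):
        assert volume_at_time(model, 5.0, 0.0) == 0.0

    def test_closed_form_value(self, model):
        # sqrt(0.1*25*10 + 4) - 2 = sqrt(29) - 2, frozen from hand algebra
        assert volume_at_time(model, 5.0, 10.0) == pytest.approx(math.sqrt(29) - 2)

    def test_square_root_law_when_no_membrane_resistance(self):
        m = FiltrationModel(k=0.08, Ve=0.0)
        tau = np.array([1.0, 4.0, 16.0])
        np.testing.assert_allclose(
            volume_at_time(m, 10.0, tau), 10.0 * np.sqrt(0.08 * tau), rtol=1e-12
        )

    @pytest.mark.parametrize("k", [0.005, 0.05, 0.5])
    @pytest.mark.parametrize("Ve", [0.2, 2.0, 20.0])
    @pytest.mark.parametrize("A", [5.0, 38.47])
    def test_matches_ode_integration(self, k, Ve, A):
        """Small-step integration of the rate law reproduces the closed form
        to 1e-4 uL across parameters spanning two orders of magnitude."""
        m = FiltrationModel(k=k, Ve=Ve)
        for tau in (1.0, 10.0, 60.0):
            assert volume_at_time(m, A, tau) == pytest.approx(
                ode_volume(m, A, tau), abs=1e-4
            )

    def test_negative_time_rejected(self, model):
        with pytest.raises(ValueError):
            volume_at_time(model, 5.0, -1.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(m=models, A=areas)
    def test_curve_is_nondecreasing_and_concave(self, m, A):
        tau = np.linspace(0.0, 60.0, 121)
        v = volume_at_time(m, A, tau)
        dv = np.diff(v)
        assert np.all(dv >= -1e-12)
        assert np.all(np.diff(dv) <= 1e-9)


class TestRelativeRate:
    def test_hand_value(self):
        m = FiltrationModel(k=0.1, Ve=0.0)
        assert relative_rate_q(m, A=5.0, V=5.0) == pytest.approx(0.05)

    def test_halves_when_v_term_doubles(self, model):
        # q ~ 1/(V(V+Ve)): pick volumes so the product doubles exactly
        v1 = 2.0
        prod = v1 * (v1 + model.Ve)
        v2 = (-model.Ve + math.sqrt(model.Ve**2 + 8 * prod)) / 2  # V2(V2+Ve)=2*prod
        q1 = relative_rate_q(model, 5.0, v1)
        q2 = relative_rate_q(model, 5.0, v2)
        assert q2 == pytest.approx(q1 / 2, rel=1e-10)

    def test_nonpositive_volume_rejected(self, model):
        with pytest.raises(ValueError):
            relative_rate_q(model, 5.0, 0.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(m=models, A=areas)
    def test_q_decreases_along_the_curve(self, m, A):
        tau = np.linspace(0.5, 60.0, 60)
        q = relative_rate_q(m, A, volume_at_time(m, A, tau))
        assert np.all(np.diff(q) < 0)


class TestSteadyState:
    def test_zero_area_gives_zero_volume(self, model):
        assert steady_state_volume(model, 0.0) == pytest.approx(0.0)

    def test_hand_values(self, model):
        # sqrt(10*0.1*25 + 0.25*4) - 1 = sqrt(26) - 1
        assert steady_state_volume(model, 5.0) == pytest.approx(math.sqrt(26) - 1)
        m0 = FiltrationModel(k=0.1, Ve=0.0)
        assert steady_state_volume(m0, 10.0) == pytest.approx(10.0)  # A*sqrt(10k)

    def test_threshold_reached_exactly_at_vq(self, model):
        vq = steady_state_volume(model, 5.0)
        assert relative_rate_q(model, 5.0, vq) == pytest.approx(model.q_th, rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(m=models, A=areas)
    def test_defining_identity(self, m, A):
        """Vq (Vq + Ve) = k A^2 / (2 q_th) to relative 1e-10."""
        vq = steady_state_volume(m, A)
        rhs = m.k * A**2 / (2 * m.q_th)
        assert vq * (vq + m.Ve) == pytest.approx(rhs, rel=1e-10)

    def test_time_round_trip(self, model):
        tq = steady_state_time(model, 5.0)
        assert volume_at_time(model, 5.0, tq) == pytest.approx(
            steady_state_volume(model, 5.0), abs=1e-9
        )

    def test_time_bounds(self):
        """tau_q spans [1/(2 q_th), 1/q_th): 10 min at Ve=0 up to (but never
        reaching) 20 min in the membrane-dominated limit — the separation
        always completes within 20 min at the 5 %/min threshold."""
        assert steady_state_time(FiltrationModel(k=0.3, Ve=0.0), 12.0) == pytest.approx(10.0)
        big_ve = steady_state_time(FiltrationModel(k=0.3, Ve=1e6), 12.0)
        assert 10.0 < big_ve < 20.0
        assert big_ve == pytest.approx(20.0, rel=1e-2)

    def test_zero_area_time_rejected(self, model):
        with pytest.raises(ValueError):
            steady_state_time(model, 0.0)


class TestDerivatives:
    def test_linear_regime(self):
        m = FiltrationModel(k=0.1, Ve=0.0)
        assert dVq_dA(m, 7.0) == pytest.approx(math.sqrt(10 * 0.1))
        assert d2Vq_dA2(m, 7.0) == 0.0

    def test_hand_value(self, model):
        assert dVq_dA(model, 5.0) == pytest.approx(5 / math.sqrt(26), rel=1e-12)

    @pytest.mark.parametrize("Ve", [0.0, 0.5, 2.0, 20.0])
    @pytest.mark.parametrize("k", [0.005, 0.5])
    def test_match_finite_differences(self, k, Ve):
        """First derivative against a central difference of Vq; curvature
        against a central difference of the (just-verified) first
        derivative, which avoids the cancellation of a second difference."""
        m = FiltrationModel(k=k, Ve=Ve)
        step = 1e-4
        for A in (2.0, 10.0, 40.0):
            fd1 = (steady_state_volume(m, A + step) - steady_state_volume(m, A - step)) / (2 * step)
            fd2 = (dVq_dA(m, A + step) - dVq_dA(m, A - step)) / (2 * step)
            assert dVq_dA(m, A) == pytest.approx(fd1, rel=1e-5)
            if Ve > 0:
                assert d2Vq_dA2(m, A) == pytest.approx(fd2, rel=1e-5)
            else:
                assert abs(fd2) < 1e-9

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(m=models, A=areas)
    def test_signs(self, m, A):
        assert dVq_dA(m, A) > 0
        assert d2Vq_dA2(m, A) >= 0
        if m.Ve > 0:
            assert d2Vq_dA2(m, A) > 0


class TestTypeInvariants:
    @pytest.mark.parametrize(
        "ctor, kwargs",
        [
            (FluidProperties, dict(gamma=-0.05, theta=27.0, mu=1e-3)),
            (FluidProperties, dict(gamma=0.05, theta=200.0, mu=1e-3)),
            (CakeProperties, dict(r=-1.0, v=0.5)),
            (CakeProperties, dict(r=1e12, v=0.0)),
            (FiltrationModel, dict(k=0.1, Ve=-1.0)),
            (FiltrationModel, dict(k=0.1, q_th=0.0)),
            (DeviceGeometry, dict(h=80.0, w=50.0)),  # bounded width <= height
            (DeviceGeometry, dict(h=80.0, A=-1.0)),
        ],
    )
    def test_invalid_fields_rejected(self, ctor, kwargs):
        with pytest.raises(ValueError):
            ctor(**kwargs)
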