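import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from penpress.click_io import FlowSeries
from penpress.device_model import (
    DeviceGeometry,
    FluidProps,
    SpringCurve,
    calibrate_spring,
    needle_pressure_drop,
    needle_radius_from_flow,
    needle_to_syringe_drop_ratio,
    outlet_pressure,
    spring_force_from_outlet,
)
from penpress.errors import InvalidInputError
from penpress.units import ATM, UL, UL_PER_S


@pytest.fixture
def water():
    return FluidProps(mu=1.0e-3, rho=1000.0)


class TestNeedlePressureDrop:
    def test_zero_flow_zero_drop(self, geom, water):
        assert needle_pressure_drop(0.0, geom, water) == 0.0

    def test_hand_computed_reference_value(self, water):
        # Q = 100 µL/s, L = 6 mm, r_n = 66.5 µm, alpha = 2:
        # viscous = 8·1e-3·6e-3·1e-7/(π·(66.5e-6)^4) ≈ 7.81e4 Pa
        # kinetic = 2·1000·(1e-7)²/(2π²·(66.5e-6)^4) ≈ 5.18e4 Pa
        geom = DeviceGeometry(r_n=66.5e-6, L_n=6e-3, alpha_kinetic=2.0)
        total = needle_pressure_drop(100 * UL_PER_S, geom, water)
        visc_only = needle_pressure_drop(
            100 * UL_PER_S, DeviceGeometry(r_n=66.5e-6, L_n=6e-3, alpha_kinetic=0.0), water
        )
        assert visc_only == pytest.approx(7.81e4, rel=1e-3)
        assert total - visc_only == pytest.approx(5.18e4, rel=1e-3)
        assert total == pytest.approx(1.30e5, rel=2e-3)

    def test_polynomial_structure_under_flow_doubling(self, geom, water):
        q = 50 * UL_PER_S
        visc_geom = DeviceGeometry(alpha_kinetic=0.0)
        visc1 = needle_pressure_drop(q, visc_geom, water)
        visc2 = needle_pressure_drop(2 * q, visc_geom, water)
        assert visc2 == pytest.approx(2 * visc1)
        kin1 = needle_pressure_drop(q, geom, water) - visc1
        kin2 = needle_pressure_drop(2 * q, geom, water) - visc2
        assert kin2 == pytest.approx(4 * kin1)

    def test_negative_flow_rejected(self, geom, water):
        with pytest.raises(InvalidInputError):
            needle_pressure_drop(-1e-9, geom, water)

    def test_kinetic_term_same_order_as_viscous_at_150uLs(self, geom, water):
        # at the largest air flow rates the entry/kinetic term matters
        visc = needle_pressure_drop(
            150 * UL_PER_S, DeviceGeometry(alpha_kinetic=0.0), water
        )
        kin = needle_pressure_drop(150 * UL_PER_S, geom, water) - visc
        assert 0.1 < kin / visc < 10

    def test_needle_drop_dominates_syringe_drop(self, geom, water):
        assert needle_to_syringe_drop_ratio(100 * UL_PER_S, geom, water) > 1e3


class TestPressureBalance:
    def test_static_balance(self, geom, water):
        assert outlet_pressure(3.0, 0.0, geom, water) == pytest.approx(
            3.0 / (np.pi * geom.r_s**2)
        )

    def test_balance_point_gives_zero_gauge(self, geom, water):
        q = 120 * UL_PER_S
        F = np.pi * geom.r_s**2 * needle_pressure_drop(q, geom, water)
        assert outlet_pressure(F, q, geom, water) == pytest.approx(0.0, abs=1e-9)

    def test_static_spring_force(self, geom, water):
        F = spring_force_from_outlet(ATM, 0.0, geom, water)
        assert F == pytest.approx(np.pi * geom.r_s**2 * ATM)

    @given(
        F=st.floats(min_value=0.0, max_value=40.0),
        q_uL=st.floats(min_value=0.0, max_value=300.0),
    )
    def test_outlet_and_spring_force_are_exact_inverses(self, F, q_uL):
        geom, water = DeviceGeometry(), FluidProps()
        q = q_uL * UL_PER_S
        p2 = outlet_pressure(F, q, geom, water)
        assert spring_force_from_outlet(p2, q, geom, water) == pytest.approx(
            F, abs=1e-9
        )

    def test_larger_flow_needs_larger_force(self, geom, water):
        f0 = spring_force_from_outlet(ATM, 0.0, geom, water)
        f150 = spring_force_from_outlet(ATM, 150 * UL_PER_S, geom, water)
        expected = np.pi * geom.r_s**2 * needle_pressure_drop(150 * UL_PER_S, geom, water)
        assert f150 - f0 == pytest.approx(expected)


class TestNeedleRadiusCalibration:
    def test_inverse_of_pressure_drop_to_roundoff(self, geom, water):
        q = 100 * UL_PER_S
        dp = needle_pressure_drop(q, geom, water)
        r = needle_radius_from_flow(dp, q, geom.L_n, water, geom.alpha_kinetic)
        assert r == pytest.approx(geom.r_n, rel=1e-12)

    def test_pressure_scaling_law(self, water):
        q, L = 100 * UL_PER_S, 6e-3
        r1 = needle_radius_from_flow(1.0e5, q, L, water)
        r2 = needle_radius_from_flow(4.0e5, q, L, water)
        assert r2 == pytest.approx(r1 * 4 ** (-0.25))

    def test_pure_poiseuille_limit(self, water):
        q, L, dp = 100 * UL_PER_S, 6e-3, 1.0e5
        r = needle_radius_from_flow(dp, q, L, water, alpha_kinetic=0.0)
        assert r == pytest.approx((8 * water.mu * L * q / (np.pi * dp)) ** 0.25)


class TestSpringCurve:
    def test_flat_extrapolation_warns(self):
        curve = SpringCurve([0.0, 1e-7], [10.0, 5.0])
        with pytest.warns(UserWarning, match="extrapolation"):
            val = curve(2e-7)
        assert val == 5.0

    def test_calibration_recovers_linear_truth(self, spring, air_pair, geom, fluid):
        cal = calibrate_spring([inj.flow for inj in air_pair], geom, fluid)
        truth = spring(cal.V_knots)
        assert np.max(np.abs(cal.F_knots / truth - 1)) < 1e-3

    def test_pooling_identical_series_is_idempotent(self, air_pair, geom, fluid):
        one = calibrate_spring([air_pair[0].flow], geom, fluid)
        two = calibrate_spring([air_pair[0].flow, air_pair[0].flow], geom, fluid)
        assert np.allclose(one.F_knots, two.F_knots)

    def test_isotonic_projection_restores_monotonicity(self, air_pair, geom, fluid):
        flow = air_pair[0].flow
        q = flow.Q.copy()
        q[10] *= 1.5  # one outlier interval
        noisy = FlowSeries(flow.t_mid, q, flow.V_mid, flow.volume_per_click)
        cal = calibrate_spring([noisy], geom, fluid)
        assert np.all(np.diff(cal.F_knots) <= 1e-9)
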