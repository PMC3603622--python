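"""Single-fiber ventricle: kinematics, stress laws, pressures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coroflow import heart
from coroflow.heart import HeartParams, HeartState


P = HeartParams()


class TestFiberStretch:
    def test_reference_volume_is_identity(self):
        lam_f, lam_r, l_s = heart.fiber_stretch(P.V_lv0, P)
        assert lam_f == pytest.approx(1.0)
        assert lam_r == pytest.approx(1.0)
        assert l_s == pytest.approx(P.l_s0)

    def test_dilated_ventricle(self):
        # V=120 mL, V0=60 mL, Vw=200 mL -> ((120+66.67)/(60+66.67))^(1/3)
        lam_f, _, _ = heart.fiber_stretch(120e-6, P)
        assert lam_f == pytest.approx(1.1381, abs=2e-4)

    @given(st.floats(min_value=5e-6, max_value=500e-6))
    @settings(max_examples=50, deadline=None)
    def test_incompressibility(self, V):
        lam_f, lam_r, _ = heart.fiber_stretch(V, P)
        assert lam_r * lam_f ** 2 == pytest.approx(1.0, rel=1e-12)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(heart.InvalidStateError):
            heart.fiber_stretch(0.0, P)


class TestStressFunctions:
    @pytest.mark.parametrize("l_s, expected", [
        (1.5e-6, 0.0),                  # zero-stress sarcomere length
        (1.4e-6, 0.0),                  # slack: tension only
        (2.0e-6, 90e3 * math.tanh(1.2) ** 2),   # ~62.5 kPa
    ])
    def test_g1_length(self, l_s, expected):
        assert heart.g1_length(l_s, P) == pytest.approx(expected, rel=1e-6)

    def test_g1_bounded_by_scale(self):
        assert heart.g1_length(2.6e-6, P) < P.sigma_a0
        assert heart.g1_length(1e-3, P) <= P.sigma_a0  # saturates at the scale

    @pytest.mark.parametrize("t_a, expected", [
        (-0.01, 0.0),
        (0.4, 0.0),                     # t_max boundary
        (0.55, 0.0),
        (0.2, math.tanh(0.2 / 0.075) ** 2 * math.tanh(0.2 / 0.075) ** 2),  # 0.9610
    ])
    def test_g2_activation(self, t_a, expected):
        assert heart.g2_activation(t_a, P) == pytest.approx(expected, abs=1e-12)

    def test_g2_derived_value(self):
        # mid-activation with t_r = t_d = 75 ms, t_max = 0.4 s: tanh^4(8/3)
        assert heart.g2_activation(0.2, P) == pytest.approx(0.96211, abs=1e-4)

    @pytest.mark.parametrize("v_s, expected", [
        (0.0, 1.0),
        (10e-6, 0.0),                   # unloaded shortening velocity
        (5e-6, 1.0 / 3.0),
    ])
    def test_g3_velocity(self, v_s, expected):
        assert heart.g3_velocity(v_s, P) == pytest.approx(expected, rel=1e-12)

    def test_g3_pole_clamped(self):
        out = heart.g3_velocity(-1.5 * P.v_s0 / P.c_v, P)
        assert math.isfinite(out)

    def test_active_stress_zero_after_activation(self):
        assert heart.active_stress(2.2e-6, 0.0, 0.45, P) == 0.0

    def test_active_stress_product(self):
        sig = heart.active_stress(2.0e-6, 0.0, 0.2, P)
        g2 = math.tanh(0.2 / 0.075) ** 2 * math.tanh(0.2 / 0.075) ** 2
        assert sig == pytest.approx(90e3 * math.tanh(1.2) ** 2 * g2, rel=1e-9)

    def test_contractility_scales_linearly(self):
        from dataclasses import replace
        base = heart.active_stress(2.0e-6, 1e-6, 0.2, P)
        scaled = heart.active_stress(2.0e-6, 1e-6, 0.2, replace(P, c=1.4))
        assert scaled == pytest.approx(1.4 * base, rel=1e-12)

    def test_passive_zero_at_reference(self):
        sig_p, sig_r = heart.passive_stresses(1.0, 1.0, P)
        assert sig_p == 0.0 and sig_r == 0.0

    def test_passive_fiber_extension(self):
        sig_p, _ = heart.passive_stresses(1.1, 1.1 ** -2, P)
        assert sig_p == pytest.approx(0.9e3 * (math.e ** 1.2 - 1.0), rel=1e-9)

    def test_passive_radial_compression(self):
        # fiber compressed (lam_f < 1) -> radial branch engages; lam_r = 0.9
        _, sig_r = heart.passive_stresses(0.95, 0.9, P)
        assert sig_r == pytest.approx(0.2e3 * (math.exp(-0.9) - 1.0), rel=1e-9)
        assert sig_r < 0


class TestPressures:
    def test_lv_pressure_zero_case(self):
        assert heart.lv_pressure(2.0 * 5e3, 5e3, 60e-6, P) == 0.0

    def test_lv_pressure_value(self):
        p = heart.lv_pressure(120e3, 0.0, 60e-6, P)
        assert p == pytest.approx(40e3 * math.log(13.0 / 3.0), rel=1e-9)

    def test_lv_pressure_monotone_in_fiber_stress(self):
        ps = [heart.lv_pressure(s, 1e3, 80e-6, P) for s in (50e3, 100e3, 150e3)]
        assert ps[0] < ps[1] < ps[2]

    def test_pim_zero_case(self):
        assert heart.intramyocardial_pressure(0.0, 0.0, 60e-6, P) == 0.0

    def test_pim_weight_matches_shell_radii(self):
        cbrt = lambda v: (3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0)
        r_i, r_o = cbrt(60e-6), cbrt(260e-6)
        r_bar = cbrt(60e-6 + 200e-6 / 3.0)
        w = (r_o - r_bar) / (r_o - r_i)
        assert heart.intramyocardial_pressure(0.0, 10e3, 60e-6, P) == pytest.approx(
            w * 10e3, rel=1e-12)
        assert 0.4 < w < 0.7  # representative shell sits mid-wall

    def test_passive_pressure_zero_at_reference_volume(self):
        p, _, _ = heart.evaluate_pressures(P.V_lv0, 0.0, 0.5, P)  # diastole
        assert p == pytest.approx(0.0, abs=1e-9)


class TestAdvanceVentricle:
    def test_no_flow_conserves_volume(self):
        s = HeartState(V_lv=100e-6, l_s=2e-6)
        out = heart.advance_ventricle(s, 0.0, 0.0, 1e-3, P)
        assert out.V_lv == pytest.approx(100e-6)

    def test_volume_balance(self):
        s = HeartState(V_lv=100e-6, l_s=2e-6)
        out = heart.advance_ventricle(s, 100e-6, 0.0, 1e-3, P)
        assert out.V_lv == pytest.approx(100e-6 + 0.1e-6)

    def test_relaxes_to_passive_curve_without_activity(self):
        from dataclasses import replace
        P0 = replace(P, c=0.0)
        s = HeartState(V_lv=120e-6, l_s=heart.fiber_stretch(120e-6, P0)[2])
        for _ in range(100):
            s = heart.advance_ventricle(s, 0.0, 0.0, 1e-3, P0)
        passive, _, _ = heart.evaluate_pressures(120e-6, 0.0, 0.5, P0)
        assert s.p_lv == pytest.approx(passive, rel=1e-9)
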