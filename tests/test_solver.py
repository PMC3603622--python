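"""Coupled solver: steady limits, integrator accuracy, conservation, determinism."""

import math
from dataclasses import replace

import numpy as np
import pytest

import coroflow.solver as solver_mod
from coroflow.heart import HeartParams
from coroflow.lumped import WindkesselElement
from coroflow.network import NetworkSpec, ScenarioConfig, SegmentDef
from coroflow.solver import GlobalSystem
from coroflow.valves import ValveParams

ETA, RHO = 0.004, 1050.0


def single_segment_config(length=50e-3, radius=1e-3, E=1e9,
                          Z=1e8, Rw=1e9, Cw=1e-9, c=0.0):
    """One stiff linear-wall segment with a windkessel terminal, fed by a
    quiescent (c = 0) ventricle acting as a pressure source through the valves."""
    net = NetworkSpec(scenario="rig")
    seg = SegmentDef(name="tube", parent=None, length=length, r_prox=radius,
                     r_dist=radius, h=0.1 * radius, wall_kind="linear",
                     terminal=WindkesselElement(Z=Z, R_w=Rw, C_w=Cw), E=E)
    net.add(seg)
    heart = replace(HeartParams(), c=c)
    cfg = ScenarioConfig(name="rig", network=net, heart=heart,
                         valves=ValveParams())
    return cfg


@pytest.fixture(scope="module")
def steady_rig():
    """Constant-pressure-driven tube run to steady state."""
    old = solver_mod.PULMONARY_VENOUS_PRESSURE
    solver_mod.PULMONARY_VENOUS_PRESSURE = 15e3
    try:
        cfg = single_segment_config(Z=1e9, Rw=1e10)
        sysm = GlobalSystem(cfg, dt=1e-3)
        sysm.V_lv = 210e-6  # near the passive equilibrium of the source
        for _ in range(16):
            sysm.run_cycle(record=False)
    finally:
        solver_mod.PULMONARY_VENOUS_PRESSURE = old
    return cfg, sysm


class TestSteadyPoiseuille:
    def test_steady_gradient_matches_poiseuille(self, steady_rig):
        """Driven at constant pressure, a low-Womersley tube settles on the
        Poiseuille gradient dp/dz = -8 eta Q/(pi a^4) within 1%."""
        cfg, sysm = steady_rig
        assert sysm.seg_info["tube"]["zeta_c"] == 0.0  # alpha < 2
        Q = sysm.Q_el
        assert np.std(Q) / np.mean(Q) < 1e-3  # steady and uniform
        p = sysm.p_node
        a = math.sqrt(np.mean(sysm._end_area(p[sysm.end_node])) / math.pi)
        grad = (p[10] - p[9]) / sysm.el_dz[0]  # interior nodes
        expected = -8 * ETA * np.mean(Q) / (math.pi * a ** 4)
        assert grad == pytest.approx(expected, rel=0.01)

    def test_windkessel_steady_drop_identity(self, steady_rig):
        cfg, sysm = steady_rig
        q = sysm.Q_el[-1]
        p_term = sysm.p_node[-1]
        wk = cfg.network.segments["tube"].terminal
        assert p_term - wk.p_out == pytest.approx(q * (wk.Z + wk.R_w), rel=0.01)


def rc_relaxation_errors(dts=(1e-3, 5e-4), t_end=0.05, pc0=8.0e3):
    """Relative error of the solver's windkessel-capacitor trajectory against
    an independent continuous-time oracle (solve_ivp of the same physics).

    The single-element rig is started with the terminal capacitor perturbed
    off its cascade value, so the dominant dynamics is the RC relaxation.
    The micrometre-scale tube also carries an L-C wave mode far above any
    resolvable frequency, which backward Euler (correctly) damps, so the
    comparison is made on the slow capacitor state.
    """
    from scipy.integrate import solve_ivp

    cfg = single_segment_config(length=2.4e-3, radius=1e-3,
                                Z=2e8, Rw=2e9, Cw=5e-9)

    def pc_of(dt):
        sysm = GlobalSystem(cfg, dt=dt)
        sysm.p_lump[0] = pc0
        for _ in range(round(t_end / dt)):
            sysm.step()
        return sysm.p_lump[0]

    ref_sys = GlobalSystem(cfg, dt=1e-3)  # only for geometry/coefficients
    assert ref_sys.n_elements == 1
    dz = ref_sys.el_dz[0]
    wk = cfg.network.segments["tube"].terminal
    law = ref_sys.seg_info["tube"]["wall"]
    cv0 = law.compliance() * dz / 2.0  # node control-volume compliances

    def rhs(t, y):
        p0, p1, pc, Q = y
        A = law.area(0.5 * (p0 + p1))
        k_visc = 4 * math.pi * ETA / (RHO * A)
        k_p = (A / RHO) * 0.5 / dz
        leak = (1246.76 - p0) / 1e12  # closed aortic valve leak
        return [(-Q + leak) / cv0,
                (Q - (p1 - pc) / wk.Z) / cv0,
                ((p1 - pc) / wk.Z - (pc - wk.p_out) / wk.R_w) / wk.C_w,
                -k_visc * Q - k_p * (p1 - p0)]

    sol = solve_ivp(rhs, (0, t_end), [9.3e3, 9.3e3, pc0, 0.0],
                    rtol=1e-11, atol=1e-9, method="LSODA")
    exact = sol.y[2, -1]
    return {dt: abs(pc_of(dt) - exact) / abs(exact) for dt in dts}


class TestIntegratorOracle:
    def test_backward_euler_converges_to_continuous_solution(self):
        """The implicit update of the windkessel state tracks the continuous
        dynamics (independent solve_ivp oracle) with first-order accuracy."""
        err = rc_relaxation_errors()
        assert err[1e-3] < 1e-3
        assert err[5e-4] < 0.7 * err[1e-3]  # first-order decay toward the oracle


class TestFixedPoint:
    def test_uniform_closed_state_is_stationary(self):
        """With both valves closed, no intramyocardial load and every boundary
        at the network pressure, the state only moves at the closed-valve leak
        scale."""
        cfg = single_segment_config(c=0.0, Rw=1e9)
        p_eq = 9.3e3
        net = cfg.network
        net.segments["tube"].terminal = WindkesselElement(
            Z=1e8, R_w=1e9, C_w=1e-9, p_out=p_eq)
        sysm = GlobalSystem(cfg, dt=1e-3)
        V0 = 150e-6  # passive p_lv between p_pulm and the network pressure
        sysm.V_lv = V0
        import coroflow.heart as H
        sysm.p_lv = H.evaluate_pressures(V0, 0.0, 0.5, cfg.heart)[0]
        assert 1200.0 < sysm.p_lv < p_eq
        p_before = sysm.p_node.copy()
        for _ in range(100):
            sysm.step()
        # drift only at the closed-valve leak scale dp/R_c ~ 1e-8 m^3/s
        assert np.max(np.abs(sysm.p_node - p_before)) < 10.0  # Pa over 0.1 s
        assert abs(sysm.V_lv - V0) < 1e-8
        assert np.max(np.abs(sysm.Q_el)) < 1e-8


class TestDeterminism:
    def test_identical_configs_bitwise_identical(self):
        from coroflow.network import apply_scenario

        a = GlobalSystem(apply_scenario("healthy"), dt=1e-3)
        b = GlobalSystem(apply_scenario("healthy"), dt=1e-3)
        ra = a.run_cycle()["rec"]
        rb = b.run_cycle()["rec"]
        assert np.array_equal(ra["P"], rb["P"])
        assert np.array_equal(ra["Q"], rb["Q"])
        assert np.array_equal(ra["V_lv"], rb["V_lv"])


class TestConservation:
    def test_heart_volume_balance_over_cycle(self, healthy_run):
        r = healthy_run.raw
        net = float(np.sum(r.Q_mv - r.Q_av) * r.dt)
        assert abs(net) / r.stroke_volume < 1e-3

    def test_segment_mass_balance_over_cycle(self, healthy_run):
        """Net inflow minus outflow of a segment over the converged cycle is
        the (tiny) wall-storage drift: < 0.1% of throughput."""
        r = healthy_run.raw
        for seg in ("LMCA", "sys08 thoracic aorta A", "LAD_b"):
            els = r.seg_info[seg]["elements"]
            qin = r.Q[els[0]]
            qout = r.Q[els[-1]]
            net = abs(np.sum(qin - qout) * r.dt)
            thru = abs(np.mean(qin)) * r.T
            assert net / thru < 1e-3

    def test_stroke_volume_consistent_with_ejected_volume(self, healthy_run):
        r = healthy_run.raw
        ejected = float(np.sum(r.Q_av[r.systole]) * r.dt)
        assert ejected == pytest.approx(r.stroke_volume, rel=0.01)
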