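"""Fully coupled 0D/1D assembly and implicit time integration.

All unknowns -- ventricular volume and pressure, valve flows, 1D nodal
pressures, 1D element flows and lumped compartment pressures -- are solved
simultaneously each time step with a single sparse direct solve (backward
Euler). Nonlinear terms are Picard-linearised about the previous step:

* wall compliance ``C(p)`` and areas are evaluated at the previous nodal
  pressures;
* the convective and axial-diffusion momentum terms are evaluated explicitly
  (they are small in the subcritical regime simulated here);
* the stenosis turbulence term ``|Q|Q`` becomes ``|Q_prev| Q``;
* the ventricular pressure is linearised in cavity volume and sarcomere
  shortening velocity, which couples it implicitly to both valve flows (the
  force-velocity relation then acts as a stabilising internal resistance);
* valve open/closed states switch once per step based on the previous
  solution.

The spatial scheme is a staggered grid: pressures live on nodes, flows on
2.5 mm elements. Mass balance at a node lumps the compliance of the adjacent
half-elements; momentum on an element connects its two end pressures. At
junctions the shared node enforces pressure continuity and flow conservation.
Element ordering is segment-major, proximal to distal, so the sparsity
pattern is deterministic and runs are bit-reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from . import heart as _heart
from .heart import HeartParams
from .lumped import CoronaryBed, WindkesselElement, PULMONARY_VENOUS_PRESSURE
from .network import ScenarioConfig, RHO, ETA
from .valves import ValveParams, aortic_resistance, next_aortic_state
from .wall import CoronaryWallLaw, LinearWallLaw, P_PHYS
from .wave1d import womersley_alpha, core_fraction, convective_delta

_log = logging.getLogger(__name__)

KIND_LINEAR, KIND_LANGEWOUTERS = 0, 1


class SolverError(RuntimeError):
    pass


@dataclass
class SimulationResult:
    """Final-cycle time series of a run plus per-cycle convergence history.

    ``P`` has one row per 1D node, ``Q`` one row per element; heart channels
    are 1D arrays over the final cycle. Helper accessors map (segment name,
    arc-length position) to the stored rows.
    """

    config: ScenarioConfig
    dt: float
    T: float
    t: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    V_lv: np.ndarray
    p_lv: np.ndarray
    p_im: np.ndarray
    Q_mv: np.ndarray
    Q_av: np.ndarray
    av_open: np.ndarray
    seg_info: dict[str, dict[str, Any]]
    cycles: int
    converged: bool
    history: list[dict[str, float]]
    _system: "GlobalSystem | None" = field(default=None, repr=False)

    # -- channel accessors ------------------------------------------------
    def _seg(self, name: str) -> dict[str, Any]:
        try:
            return self.seg_info[name]
        except KeyError:
            raise KeyError(f"unknown segment {name!r}; known: {sorted(self.seg_info)}")

    def node_at(self, segment: str, pos: float = 0.0) -> int:
        info = self._seg(segment)
        return int(info["nodes"][np.argmin(np.abs(info["z_nodes"] - pos))])

    def element_at(self, segment: str, pos: float = 0.0) -> int:
        info = self._seg(segment)
        return int(info["elements"][np.argmin(np.abs(info["z_elements"] - pos))])

    def pressure(self, segment: str, pos: float = 0.0) -> np.ndarray:
        """Pressure trace (Pa) at the node nearest arc-length ``pos`` (m)."""
        return self.P[self.node_at(segment, pos)]

    def flow(self, segment: str, pos: float = 0.0) -> np.ndarray:
        """Flow trace (m^3/s) at the element nearest ``pos``."""
        return self.Q[self.element_at(segment, pos)]

    def area(self, segment: str, pos: float = 0.0) -> np.ndarray:
        """Lumen area trace (m^2) from the wall law at the local pressure."""
        info = self._seg(segment)
        return info["wall"].area(self.pressure(segment, pos))

    def velocity(self, segment: str, pos: float = 0.0) -> np.ndarray:
        """Cross-section mean velocity Q/A (m/s)."""
        return self.flow(segment, pos) / self.area(segment, pos)

    def wall_shear(self, segment: str, pos: float = 0.0) -> np.ndarray:
        """Wall shear stress trace (Pa) from the profile closure."""
        from .wave1d import wall_shear as _tw
        info = self._seg(segment)
        iel = np.argmin(np.abs(info["z_elements"] - pos))
        e = int(info["elements"][iel])
        sysm = self._system
        i, j = sysm.el_i[e], sysm.el_j[e]
        dpdz = (self.P[j] - self.P[i]) / sysm.el_dz[e]
        p_mid = 0.5 * (self.P[i] + self.P[j])
        A = info["wall"].area(p_mid)
        a = np.sqrt(A / math.pi)
        return _tw(self.Q[e], A, dpdz, a, info["zeta_c"], ETA)

    @property
    def systole(self) -> np.ndarray:
        """Boolean mask of the ejection phase (aortic valve open)."""
        return self.av_open.astype(bool)

    @property
    def stroke_volume(self) -> float:
        """End-diastolic minus end-systolic volume, m^3."""
        return float(self.V_lv.max() - self.V_lv.min())

    @property
    def cardiac_output(self) -> float:
        """Cycle-mean aortic valve flow, m^3/s."""
        return float(self.Q_av.mean())


class GlobalSystem:
    """Assembled network + heart ready for implicit time stepping."""

    def __init__(self, config: ScenarioConfig, dt: float = 5e-4):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.config = config
        self.dt = dt
        self.heart_params: HeartParams = config.heart
        self.valve_params: ValveParams = config.valves
        self.T = self.heart_params.T
        self.n_per_cycle = round(self.T / dt)
        if abs(self.n_per_cycle * dt - self.T) > 1e-12:
            _log.debug("dt does not divide T exactly; cycle uses %d steps",
                       self.n_per_cycle)
        self.f = 1.0 / self.T
        self._discretize()
        self._build_structure()
        self._init_state()

    # ------------------------------------------------------------------
    def _wall_for(self, kind: str, a: float, h: float, E: float | None = None):
        if kind == "linear":
            return LinearWallLaw(a_p=a, h_p=h, E=E if E is not None else 0.4e6)
        if kind == "coronary":
            if self.config.coronary_wall == "linear":
                return LinearWallLaw(a_p=a, h_p=h, E=1.5e6)
            return CoronaryWallLaw(a_p=a, h_p=h)
        raise ValueError(f"unknown wall kind {kind!r}")

    def _discretize(self) -> None:
        net = self.config.network
        el_i, el_j, el_dz = [], [], []
        end_node, end_halfdz = [], []
        end_kind, end_Ap, end_Cc, end_C0, end_C1, end_pm, end_pw = ([] for _ in range(7))
        el_zeta, el_delta = [], []
        el_prev, el_next = [], []
        sten_idx, sten_coef = [], []
        seg_info: dict[str, dict[str, Any]] = {}
        node_count = 0
        seg_distal: dict[str, int] = {}

        def add_end(node, halfdz, wall):
            end_node.append(node)
            end_halfdz.append(halfdz)
            if isinstance(wall, LinearWallLaw):
                end_kind.append(KIND_LINEAR)
                end_Cc.append(wall.compliance())
                end_C0.append(0.0); end_C1.append(0.0)
                end_pm.append(0.0); end_pw.append(1.0)
                end_Ap.append(wall.A_p)
            else:
                end_kind.append(KIND_LANGEWOUTERS)
                end_Cc.append(0.0)
                end_C0.append(wall.C0); end_C1.append(wall.C1)
                end_pm.append(wall.p_m); end_pw.append(wall.p_w)
                end_Ap.append(wall.A_p)

        # topological order (scenario overlays may reorder the mapping)
        ordered: list = []
        placed: set[str] = set()
        pending = list(net.segments.values())
        while pending:
            rest = []
            for seg in pending:
                if seg.parent is None or seg.parent in placed:
                    ordered.append(seg)
                    placed.add(seg.name)
                else:
                    rest.append(seg)
            if len(rest) == len(pending):
                raise ValueError(f"cyclic or dangling parents: {[s.name for s in rest]}")
            pending = rest

        for seg in ordered:
            if seg.parent is None:
                prox = node_count
                node_count += 1
            else:
                prox = seg_distal[seg.parent]
            if seg.kind == "stenosis":
                n_e = 1
                radii = np.array([seg.sten.a0, seg.sten.a0])
            else:
                n_e = max(1, round(seg.length / 2.5e-3))
                radii = np.linspace(seg.r_prox, seg.r_dist, n_e + 1)
            dz = seg.length / n_e
            alpha = womersley_alpha(seg.mean_radius if seg.kind == "vessel"
                                    else seg.sten.a0, self.f, RHO, ETA)
            zc = core_fraction(alpha)
            dl = convective_delta(zc)
            segE = getattr(seg, "E", None)
            wall_mid = self._wall_for(seg.wall_kind, seg.mean_radius
                                      if seg.kind == "vessel" else seg.sten.a0,
                                      seg.h, segE)
            nodes = [prox]
            elements = []
            first_el = len(el_i)
            for k in range(n_e):
                j = node_count
                node_count += 1
                e = len(el_i)
                el_i.append(nodes[-1]); el_j.append(j); el_dz.append(dz)
                el_zeta.append(zc); el_delta.append(dl)
                el_prev.append(e - 1 if k > 0 else -1)
                el_next.append(e + 1 if k < n_e - 1 else -1)
                rigid = seg.kind == "stenosis"
                for end_r, node in ((radii[k], nodes[-1]), (radii[k + 1], j)):
                    w = self._wall_for(seg.wall_kind, end_r, seg.h, segE)
                    add_end(node, 0.0 if rigid else dz / 2.0, w)
                nodes.append(j)
                elements.append(e)
            if seg.kind == "stenosis":
                sten_idx.append(first_el)
                sten_coef.append(seg.sten.momentum_coefficients(alpha, ETA, RHO))
            seg_distal[seg.name] = nodes[-1]
            seg_info[seg.name] = {
                "nodes": np.array(nodes), "elements": np.array(elements),
                "z_nodes": np.linspace(0.0, seg.length, n_e + 1),
                "z_elements": (np.arange(n_e) + 0.5) * dz,
                "zeta_c": zc, "delta": dl, "alpha": alpha, "wall": wall_mid,
                "terminal": seg.terminal,
            }

        self.n_nodes = node_count
        self.n_elements = len(el_i)
        self.el_i = np.array(el_i); self.el_j = np.array(el_j)
        self.el_dz = np.array(el_dz)
        self.el_zeta = np.array(el_zeta); self.el_delta = np.array(el_delta)
        self.el_prev = np.array(el_prev); self.el_next = np.array(el_next)
        self.end_node = np.array(end_node); self.end_halfdz = np.array(end_halfdz)
        self.end_kind = np.array(end_kind)
        self.end_Ap = np.array(end_Ap); self.end_Cc = np.array(end_Cc)
        self.end_C0 = np.array(end_C0); self.end_C1 = np.array(end_C1)
        self.end_pm = np.array(end_pm); self.end_pw = np.array(end_pw)
        self.sten_idx = np.array(sten_idx, dtype=int)
        self.sten_coef = np.array(sten_coef).reshape(-1, 4)
        self.sten_Qbar = np.zeros(len(sten_idx))
        self._sten_Qacc = np.zeros(len(sten_idx))
        self.is_sten = np.zeros(self.n_elements, dtype=bool)
        self.is_sten[self.sten_idx] = True
        self.seg_info = seg_info

        # terminals
        wk_node, wk, bed_node, beds = [], [], [], []
        for seg in net.segments.values():
            term = seg.terminal
            if term is None:
                continue
            node = seg_distal[seg.name]
            if isinstance(term, WindkesselElement):
                wk_node.append(node); wk.append(term)
            elif isinstance(term, CoronaryBed):
                bed_node.append(node); beds.append(term)
        self.wk_node = np.array(wk_node, dtype=int); self.wk = wk
        self.bed_node = np.array(bed_node, dtype=int); self.beds = beds
        self.n_lump = len(wk) + 3 * len(beds)

        # unknown layout
        self.iV, self.iP_lv, self.iQmv, self.iQav = 0, 1, 2, 3
        self.node_col = 4 + np.arange(self.n_nodes)
        self.el_col = 4 + self.n_nodes + np.arange(self.n_elements)
        self.lump_col = 4 + self.n_nodes + self.n_elements + np.arange(self.n_lump)
        self.n_unknowns = 4 + self.n_nodes + self.n_elements + self.n_lump
        self.wk_lump = self.lump_col[:len(wk)] if len(wk) else np.array([], dtype=int)
        bed_base = 4 + self.n_nodes + self.n_elements + len(wk)
        self.bed_lump = bed_base + 3 * np.arange(len(beds))

    # ------------------------------------------------------------------
    def _build_structure(self) -> None:
        """Fixed (row, col) pattern; constant coefficient blocks precomputed."""
        rows, cols = [], []

        def block(r, c):
            rows.append(np.asarray(r, dtype=int))
            cols.append(np.asarray(c, dtype=int))
            return sum(len(x) for x in rows) - len(np.asarray(r))

        nN, nE = self.n_nodes, self.n_elements
        ncol, ecol = self.node_col, self.el_col

        # heart block (rows 0-3)
        hr = [0, 0, 0, 1, 1, 1, 1, 2, 2, 3, 3, 3]
        hc = [self.iV, self.iQmv, self.iQav,
              self.iP_lv, self.iV, self.iQmv, self.iQav,
              self.iQmv, self.iP_lv,
              self.iQav, self.iP_lv, int(ncol[0])]
        self.s_heart = block(hr, hc)

        # node capacitance diagonal (varying)
        self.s_nodecap = block(ncol, ncol)
        # incidence (+1 out of i, -1 into j) -- constant
        self.s_inc = block(np.concatenate([ncol[self.el_i], ncol[self.el_j]]),
                           np.concatenate([self.el_col, self.el_col]))
        self._inc_data = np.concatenate([np.ones(nE), -np.ones(nE)])
        # aortic inflow into root node -- constant
        self.s_root = block([int(ncol[0])], [self.iQav])

        # windkessel couplings -- constant
        wkn = self.node_col[self.wk_node] if len(self.wk) else np.array([], dtype=int)
        wkl = self.wk_lump
        Z = np.array([w.Z for w in self.wk]); Rw = np.array([w.R_w for w in self.wk])
        Cw = np.array([w.C_w for w in self.wk])
        self.s_wk = block(np.concatenate([wkn, wkn, wkl, wkl]),
                          np.concatenate([wkn, wkl, wkl, wkn]))
        self._wk_data = np.concatenate([1.0 / Z, -1.0 / Z,
                                        Cw / self.dt + 1.0 / Z + 1.0 / Rw, -1.0 / Z])
        self._wk_Rw, self._wk_Cw = Rw, Cw
        self._wk_pout = np.array([w.p_out for w in self.wk])

        # coronary bed couplings
        bn = self.node_col[self.bed_node] if self.beds else np.array([], dtype=int)
        pa, pm_, pv = self.bed_lump, self.bed_lump + 1, self.bed_lump + 2
        Ra = np.array([b.R_art for b in self.beds])
        Rm1 = np.array([b.R_myo1 for b in self.beds])
        Rm2 = np.array([b.R_myo2 for b in self.beds])
        Rv = np.array([b.R_ven for b in self.beds])
        Ca = np.array([b.C_art for b in self.beds])
        Cm = np.array([b.C_myo for b in self.beds])
        Cv = np.array([b.C_ven for b in self.beds])
        self._bed = dict(Ra=Ra, Rm1=Rm1, Rm2=Rm2, Rv=Rv, Ca=Ca, Cm=Cm, Cv=Cv,
                         s=np.array([b.pim_scale for b in self.beds]),
                         pout=np.array([b.p_out for b in self.beds]))
        dtv = self.dt
        self.s_bed_const = block(
            np.concatenate([bn, bn, pa, pa, pa, pm_, pm_, pm_, pv, pv]),
            np.concatenate([bn, pa, pa, bn, pm_, pm_, pa, pv, pv, pm_]))
        self._bed_const_data = np.concatenate([
            1.0 / Ra, -1.0 / Ra,
            Ca / dtv + 1.0 / Ra + 1.0 / Rm1, -1.0 / Ra, -1.0 / Rm1,
            Cm / dtv + 1.0 / Rm1 + 1.0 / Rm2, -1.0 / Rm1, -1.0 / Rm2,
            Cv / dtv + 1.0 / Rm2 + 1.0 / Rv, -1.0 / Rm2])
        # p_lv coupling of the three capacitors (varying with the mid-wall weight)
        plv_col = np.full(3 * len(self.beds), self.iP_lv, dtype=int)
        self.s_bed_plv = block(np.concatenate([pa, pm_, pv]), plv_col)

        # element momentum rows (varying)
        self.s_elm = block(np.concatenate([ecol, ecol, ecol]),
                           np.concatenate([ecol, ncol[self.el_i], ncol[self.el_j]]))

        self.rows = np.concatenate(rows)
        self.cols = np.concatenate(cols)
        self.nnz = len(self.rows)
        # slice offsets per family, in the order blocks were added
        sizes = [len(r) for r in rows]
        offs = np.concatenate([[0], np.cumsum(sizes)])
        (self.o_heart, self.o_nodecap, self.o_inc, self.o_root, self.o_wk,
         self.o_bed_const, self.o_bed_plv, self.o_elm, self._o_end) = offs

        self.data = np.zeros(self.nnz)
        self.data[self.o_inc:self.o_root] = self._inc_data
        self.data[self.o_root] = -1.0
        self.data[self.o_wk:self.o_bed_const] = self._wk_data
        self.data[self.o_bed_const:self.o_bed_plv] = self._bed_const_data

    # ------------------------------------------------------------------
    def _init_state(self) -> None:
        p0 = 9.3e3
        self.p_node = np.full(self.n_nodes, p0)
        self.Q_el = np.zeros(self.n_elements)
        # lumped compartments start on the resistive cascade from p0 to venous
        self.p_lump = np.full(self.n_lump, p0)
        for k, w in enumerate(self.wk):
            q = (p0 - w.p_out) / (w.Z + w.R_w)
            self.p_lump[k] = w.p_out + q * w.R_w
        for k, b in enumerate(self.beds):
            q = b.steady_flow(p0)
            base = len(self.wk) + 3 * k
            self.p_lump[base] = p0 - q * b.R_art
            self.p_lump[base + 1] = self.p_lump[base] - q * b.R_myo1
            self.p_lump[base + 2] = b.p_out + q * b.R_ven
        self.V_lv = 120e-6
        self.Q_mv = 0.0
        self.Q_av = 0.0
        self.t = 0.0
        self.mv_open = False
        self.av_open = False
        hp = self.heart_params
        self.p_lv, self.p_im, _ = _heart.evaluate_pressures(self.V_lv, 0.0, 0.0, hp)
        # linearised intramyocardial reference used by the bed capacitors; kept
        # separately so the per-step capacitor charge telescopes exactly over a cycle
        self.p_im_lin = self.p_im
        self.step_count = 0

    # -- wall-law vectorized evaluations --------------------------------
    def _end_compliance(self, p_ends: np.ndarray) -> np.ndarray:
        lang = self.end_kind == KIND_LANGEWOUTERS
        C = self.end_Cc.copy()
        C[lang] = (self.end_C0[lang]
                   + self.end_C1[lang]
                   / (1.0 + ((p_ends[lang] - self.end_pm[lang]) / self.end_pw[lang]) ** 2))
        return C

    def _end_area(self, p_ends: np.ndarray) -> np.ndarray:
        lang = self.end_kind == KIND_LANGEWOUTERS
        A = self.end_Ap + self.end_Cc * (p_ends - P_PHYS)
        if np.any(lang):
            pmL, pwL = self.end_pm[lang], self.end_pw[lang]
            A[lang] = (self.end_Ap[lang]
                       + self.end_C0[lang] * (p_ends[lang] - P_PHYS)
                       + self.end_C1[lang] * pwL
                       * (np.arctan((p_ends[lang] - pmL) / pwL)
                          - np.arctan((P_PHYS - pmL) / pwL)))
        if np.any(A <= 0):
            raise SolverError("lumen area collapsed (non-positive)")
        return A

    # ------------------------------------------------------------------
    def step(self) -> None:
        """One backward-Euler step of the fully coupled system."""
        dt, hp, vp = self.dt, self.heart_params, self.valve_params
        t_new = self.t + dt
        t_a = math.fmod(t_new, self.T)

        # heart linearisation about the previous state
        g = _heart.dls_dV(self.V_lv, hp)
        v_hat = -g * (self.Q_mv - self.Q_av)
        pole = -hp.v_s0 / hp.c_v
        if v_hat <= pole:  # force-velocity pole: clamp (transients only)
            _log.debug("shortening velocity %.3e clamped at the g3 pole", v_hat)
            v_hat = 0.99 * pole
        p_hat, _, sig_r = _heart.evaluate_pressures(self.V_lv, v_hat, t_a, hp)
        aV, av = _heart.pressure_partials(self.V_lv, v_hat, t_a, hp)
        r_i, r_o, r_bar = _heart.shell_radii(self.V_lv, hp)
        w_im = (r_o - r_bar) / (r_o - r_i)

        # valve states from the previous solution
        self.mv_open = (PULMONARY_VENOUS_PRESSURE - self.p_lv) >= 0.0
        self.av_open = next_aortic_state(self.av_open, self.p_lv,
                                         self.p_node[0], self.Q_av)
        R_mv = vp.R_mv_o if self.mv_open else vp.R_mv_c
        R_av = aortic_resistance(self.av_open, vp)
        L_av = vp.L_av

        # wall state at previous pressures
        p_ends = self.p_node[self.end_node]
        C_ends = self._end_compliance(p_ends)
        A_ends = self._end_area(p_ends)
        cap = np.zeros(self.n_nodes)
        np.add.at(cap, self.end_node, C_ends * self.end_halfdz)
        A_el = 0.5 * (A_ends[0::2] + A_ends[1::2])
        # explicit convective term, interpolated within each segment only
        Qi = np.where(self.el_prev >= 0,
                      0.5 * (self.Q_el + self.Q_el[self.el_prev]), self.Q_el)
        Qj = np.where(self.el_next >= 0,
                      0.5 * (self.Q_el + self.Q_el[self.el_next]), self.Q_el)
        conv = self.el_delta * (Qj ** 2 / A_ends[1::2]
                                - Qi ** 2 / A_ends[0::2]) / self.el_dz
        Qp = np.where(self.el_prev >= 0, self.Q_el[self.el_prev], self.Q_el)
        Qx = np.where(self.el_next >= 0, self.Q_el[self.el_next], self.Q_el)
        diff = ETA / RHO * (Qp - 2.0 * self.Q_el + Qx) / self.el_dz ** 2

        one_m_z = 1.0 - self.el_zeta
        k_visc = 4.0 * math.pi * ETA / (RHO * one_m_z * A_el)
        k_p = (A_el / RHO) * (1.0 + self.el_zeta) / 2.0 / self.el_dz
        diag_el = 1.0 / dt + k_visc
        rhs_el = self.Q_el / dt - conv + diff
        ci, cj = -k_p, k_p.copy()
        if len(self.sten_idx):
            si = self.sten_idx
            cv, ct, cp_, cm = (self.sten_coef[:, 0], self.sten_coef[:, 1],
                               self.sten_coef[:, 2], self.sten_coef[:, 3])
            diag_el[si] = 1.0 / dt + cv + ct * np.abs(self.Q_el[si])
            ci[si] = -cp_
            cj[si] = cp_
            rhs_el[si] = self.Q_el[si] / dt - cm * self.sten_Qbar

        # assemble varying blocks
        d = self.data
        d[self.o_heart:self.o_heart + 12] = [
            1.0, -dt, dt,
            1.0, -aV, av * g, -av * g,
            R_mv, 1.0,
            L_av / dt + R_av, -1.0, 1.0,
        ]
        d[self.o_nodecap:self.o_inc] = cap / dt
        if self.beds:
            b = self._bed
            s = b["s"]
            coup = -(np.concatenate([b["Ca"], b["Cm"], b["Cv"]]) / dt
                     * np.tile(s, 3) * w_im)
            d[self.o_bed_plv:self.o_elm] = coup
        d[self.o_elm:self.o_elm + self.n_elements] = diag_el
        d[self.o_elm + self.n_elements:self.o_elm + 2 * self.n_elements] = ci
        d[self.o_elm + 2 * self.n_elements:self._o_end] = cj

        # right-hand side
        rhs = np.zeros(self.n_unknowns)
        rhs[self.iV] = self.V_lv
        rhs[self.iP_lv] = p_hat - aV * self.V_lv - av * v_hat
        rhs[self.iQmv] = PULMONARY_VENOUS_PRESSURE
        rhs[self.iQav] = L_av / dt * self.Q_av
        rhs[self.node_col] = cap / dt * self.p_node
        rhs[self.el_col] = rhs_el
        if len(self.wk):
            rhs[self.wk_lump] = (self._wk_Cw / dt * self.p_lump[:len(self.wk)]
                                 + self._wk_pout / self._wk_Rw)
        if self.beds:
            b = self._bed
            s = b["s"]
            pa = self.p_lump[len(self.wk)::3][:len(self.beds)]
            pm_ = self.p_lump[len(self.wk) + 1::3][:len(self.beds)]
            pv = self.p_lump[len(self.wk) + 2::3][:len(self.beds)]
            base = s * (sig_r - self.p_im_lin)
            rhs[self.bed_lump] = b["Ca"] / dt * (pa + base)
            rhs[self.bed_lump + 1] = b["Cm"] / dt * (pm_ + base)
            rhs[self.bed_lump + 2] = (b["Cv"] / dt * (pv + base)
                                      + b["pout"] / b["Rv"])

        A = sp.coo_matrix((d, (self.rows, self.cols)),
                          shape=(self.n_unknowns, self.n_unknowns)).tocsc()
        try:
            x = splu(A).solve(rhs)
        except RuntimeError as err:
            raise SolverError(f"direct solve failed at t={t_new:.4f}: {err}") from err
        if not np.all(np.isfinite(x)):
            bad = np.where(~np.isfinite(x))[0][:5]
            raise SolverError(f"non-finite solution at t={t_new:.4f}, unknowns {bad}")

        # commit
        V_new = x[self.iV]
        if V_new <= 0:
            raise SolverError("cavity volume driven non-positive")
        Qmv_new, Qav_new = x[self.iQmv], x[self.iQav]
        self.p_node = x[self.node_col]
        self.Q_el = x[self.el_col]
        self.p_lump = x[self.lump_col] if self.n_lump else self.p_lump
        v_new = -g * (Qmv_new - Qav_new)
        p_lv_new, p_im_new, _ = _heart.evaluate_pressures(V_new, v_new, t_a, hp)
        self.V_lv, self.Q_mv, self.Q_av = V_new, Qmv_new, Qav_new
        self.p_lv = x[self.iP_lv]
        self.p_im = p_im_new
        self.p_im_lin = sig_r + w_im * x[self.iP_lv]
        self.t = t_new
        self.step_count += 1
        if len(self.sten_idx):
            self._sten_Qacc += self.Q_el[self.sten_idx] * dt

    # ------------------------------------------------------------------
    def run_cycle(self, record: bool = True) -> dict[str, Any]:
        """Integrate one cardiac cycle; returns recorded channels and summary."""
        n = self.n_per_cycle
        rec = None
        if record:
            rec = {
                "t": np.empty(n), "P": np.empty((self.n_nodes, n)),
                "Q": np.empty((self.n_elements, n)),
                "V_lv": np.empty(n), "p_lv": np.empty(n), "p_im": np.empty(n),
                "Q_mv": np.empty(n), "Q_av": np.empty(n),
                "av_open": np.empty(n, dtype=bool),
            }
        for k in range(n):
            self.step()
            if record:
                rec["t"][k] = self.t
                rec["P"][:, k] = self.p_node
                rec["Q"][:, k] = self.Q_el
                rec["V_lv"][k] = self.V_lv
                rec["p_lv"][k] = self.p_lv
                rec["p_im"][k] = self.p_im
                rec["Q_mv"][k] = self.Q_mv
                rec["Q_av"][k] = self.Q_av
                rec["av_open"][k] = self.av_open
        if len(self.sten_idx):
            self.sten_Qbar = self._sten_Qacc / (n * self.dt)
            self._sten_Qacc = np.zeros_like(self.sten_Qbar)
        summary = {
            "stroke_volume": float(rec["V_lv"].max() - rec["V_lv"].min()) if record else np.nan,
            "mean_aortic_pressure": float(rec["P"][0].mean()) if record else np.nan,
            "mean_Q_av": float(rec["Q_av"].mean()) if record else np.nan,
        }
        if record and len(self.bed_node):
            q_cor = 0.0
            for name in ("LMCA", "RCA_b"):
                if name in self.seg_info:
                    q_cor += float(rec["Q"][self.seg_info[name]["elements"][0]].mean())
            summary["mean_coronary_flow"] = q_cor
        return {"rec": rec, "summary": summary}


def run_to_periodic(config: ScenarioConfig, dt: float = 5e-4, max_cycles: int = 30,
                    tol: float = 1e-3) -> SimulationResult:
    """Integrate whole cycles until stroke volume and mean aortic pressure
    change by less than ``tol`` (relative) between successive cycles."""
    sysm = GlobalSystem(config, dt=dt)
    prev = None
    converged = False
    history: list[dict[str, float]] = []
    out = None
    for cyc in range(1, max_cycles + 1):
        out = sysm.run_cycle(record=True)
        s = out["summary"]
        s["cycle"] = cyc
        history.append(s)
        if prev is not None:
            deltas = []
            for key in ("stroke_volume", "mean_aortic_pressure",
                        "mean_coronary_flow"):
                if key in s:
                    deltas.append(abs(s[key] - prev[key])
                                  / max(abs(prev[key]), 1e-12))
            s["max_delta"] = max(deltas)
            if s["max_delta"] < tol:
                converged = True
                break
        prev = s
    if not converged:
        _log.warning("run %r not converged after %d cycles",
                     config.name, len(history))
    rec = out["rec"]
    return SimulationResult(
        config=config, dt=dt, T=sysm.T, t=rec["t"], P=rec["P"], Q=rec["Q"],
        V_lv=rec["V_lv"], p_lv=rec["p_lv"], p_im=rec["p_im"],
        Q_mv=rec["Q_mv"], Q_av=rec["Q_av"], av_open=rec["av_open"],
        seg_info=sysm.seg_info, cycles=len(history), converged=converged,
        history=history, _system=sysm)
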