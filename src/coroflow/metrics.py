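"""Post-processing: FFR, coronary flow ratios, wall-law difference, summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .solver import SimulationResult

MMHG = 133.322


def ffr(p_distal: np.ndarray, p_proximal: np.ndarray) -> float:
    """Fractional flow reserve: cycle-mean distal over proximal pressure.

    Computed over one converged hyperaemic cycle; the clinical convention of
    time-averaged pressures is used.
    """
    pp = float(np.mean(p_proximal))
    if pp <= 0:
        raise ValueError("non-positive mean proximal pressure")
    return float(np.mean(p_distal)) / pp


def ffr_across_stenosis(result: SimulationResult, segment: str = "LAD_c") -> float:
    """FFR across the stenosis embedded in ``segment`` (or across the plain
    segment if no stenosis is present)."""
    names = result.seg_info
    if f"{segment}~sten" in names:
        p_prox = result.pressure(f"{segment}~prox", pos=np.inf)
        p_dist = result.pressure(f"{segment}~dist", pos=0.0)
    else:
        p_prox = result.pressure(segment, pos=0.0)
        p_dist = result.pressure(segment, pos=np.inf)
    return ffr(p_dist, p_prox)


def dias_sys_flow_ratio(Q: np.ndarray, systole: np.ndarray) -> float:
    """Maximum diastolic over maximum systolic flow.

    ``systole`` is the boolean aortic-valve-open mask. Returns NaN (with a
    warning) if the systolic maximum is not positive.
    """
    systole = np.asarray(systole, dtype=bool)
    if systole.all() or (~systole).all():
        raise ValueError("need both systolic and diastolic samples")
    q_sys = float(np.max(Q[systole]))
    q_dia = float(np.max(Q[~systole]))
    if q_sys <= 0.0:
        warnings.warn("non-positive systolic maximum; ratio undefined", stacklevel=2)
        return float("nan")
    return q_dia / q_sys


def extreme_systolic(Q: np.ndarray, systole: np.ndarray) -> float:
    """Signed systolic extreme: the value of largest magnitude during systole."""
    qs = Q[np.asarray(systole, dtype=bool)]
    return float(qs[np.argmax(np.abs(qs))])


def max_diastolic(Q: np.ndarray, systole: np.ndarray) -> float:
    return float(np.max(Q[~np.asarray(systole, dtype=bool)]))


def delta_y(y: np.ndarray, y_lin: np.ndarray) -> np.ndarray:
    """Relative wall-law difference trace, percent:

    delta_y = 100 (y - y_lin) / ((ybar + ybar_lin)/2)

    with ``ybar`` the cycle means. Antisymmetric under swapping the traces.
    """
    denom = 0.5 * (np.mean(y) + np.mean(y_lin))
    if denom == 0:
        raise ValueError("zero mean denominator")
    return 100.0 * (np.asarray(y) - np.asarray(y_lin)) / denom


def max_abs_delta_y(y: np.ndarray, y_lin: np.ndarray) -> float:
    return float(np.max(np.abs(delta_y(y, y_lin))))


@dataclass
class CycleSummary:
    """Headline numbers of one converged cycle."""

    stroke_volume_ml: float
    cardiac_output_l_min: float
    mean_aortic_pressure_mmhg: float
    pulse_pressure_mmhg: float
    systolic_pressure_mmhg: float
    diastolic_pressure_mmhg: float
    lmca_flow_ratio: float
    rca_flow_ratio: float
    cycles: int
    converged: bool

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def summarize(result: SimulationResult) -> CycleSummary:
    p_ao = result.P[0]
    sv = result.stroke_volume * 1e6
    co = result.cardiac_output * 60e3
    sysm = result.systole
    try:
        lmca = dias_sys_flow_ratio(result.flow("LMCA"), sysm)
        rca = dias_sys_flow_ratio(result.flow("RCA_b"), sysm)
    except (KeyError, ValueError):
        lmca = rca = float("nan")
    return CycleSummary(
        stroke_volume_ml=sv,
        cardiac_output_l_min=co,
        mean_aortic_pressure_mmhg=float(np.mean(p_ao)) / MMHG,
        pulse_pressure_mmhg=float(np.max(p_ao) - np.min(p_ao)) / MMHG,
        systolic_pressure_mmhg=float(np.max(p_ao)) / MMHG,
        diastolic_pressure_mmhg=float(np.min(p_ao)) / MMHG,
        lmca_flow_ratio=lmca,
        rca_flow_ratio=rca,
        cycles=result.cycles,
        converged=result.converged,
    )


def transvalvular_gradient(result: SimulationResult) -> float:
    """Mean systolic LV-to-aorta pressure difference, Pa."""
    sysm = result.systole
    return float(np.mean(result.p_lv[sysm] - result.P[0][sysm]))


def volume_audit(result: SimulationResult) -> dict[str, float]:
    """Per-cycle conservation check: net mitral-minus-aortic volume over the
    converged cycle relative to stroke volume (should be ~0 at periodicity)."""
    net_heart = float(np.sum(result.Q_mv - result.Q_av) * result.dt)
    sv = max(result.stroke_volume, 1e-12)
    return {"heart_rel": abs(net_heart) / sv}
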