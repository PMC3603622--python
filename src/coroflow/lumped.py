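"""Lumped (0D) terminal elements.

Systemic outlets end in a three-element windkessel: a wave impedance Z in
series with a parallel peripheral resistance R_w and compliance C_w draining
to a constant venous pressure. Coronary outlets end in a serial microvascular
ladder -- three compliant compartments (arteriolar, myocardial, venular)
separated by four resistances -- whose capacitors are referenced to the
intramyocardial pressure generated by the contracting ventricle. A rising
p_im squeezes volume out of the compartments and can transiently reverse
inlet flow: the systolic impediment characteristic of coronary perfusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

MMHG = 133.322

VENOUS_PRESSURE = 700.0          # Pa, constant outflow boundary
PULMONARY_VENOUS_PRESSURE = 1200.0  # Pa, LV filling source

#: resistance split of the coronary ladder (fractions of R_t)
R_SPLIT = {"art": 7.0 / 27.0, "myo1": 9.0 / 27.0, "myo2": 9.0 / 27.0, "ven": 2.0 / 27.0}

#: number of terminal coronary vessels / parallel microvascular beds
N_TERMINALS = 14

#: organ-level compartment compliances (m^3/Pa), distributed evenly over the
#: parallel beds. Per-bed use of these whole-heart values would give arterial
#: compartment time constants C*R of order 1 s -- longer than systole -- which
#: suppresses systolic coronary inflow almost completely; distributed over the
#: 14 beds the time constants fall below the cardiac phases and the
#: characteristic systolic-impediment/diastolic-surge pattern emerges.
C_ART = 0.2e-9
C_MYO = 0.53e-9
C_VEN = 0.65e-9


def wave_impedance(A_bar: float, C_bar: float, rho: float = 1050.0) -> float:
    """Characteristic impedance Z = sqrt(rho / (A_bar * C_bar)) of a vessel."""
    if A_bar <= 0 or C_bar <= 0:
        raise ValueError("area and compliance must be positive")
    return math.sqrt(rho / (A_bar * C_bar))


def total_terminal_resistance(p_art: float, p_ven: float, Q_target: float) -> float:
    """Ohm's-law total bed resistance from the mean perfusion drop and flow."""
    if Q_target <= 0:
        raise ValueError("target flow must be positive")
    return (p_art - p_ven) / Q_target


@dataclass(frozen=True)
class WindkesselElement:
    """Three-element systemic terminal: Z in series with (R_w || C_w)."""

    Z: float
    R_w: float
    C_w: float
    p_out: float = VENOUS_PRESSURE

    def __post_init__(self) -> None:
        if min(self.Z, self.R_w, self.C_w) <= 0:
            raise ValueError("Z, R_w and C_w must be positive")

    @property
    def tau(self) -> float:
        """Peripheral time constant R_w * C_w (about 2 s for systemic beds)."""
        return self.R_w * self.C_w

    def steady_pressure_drop(self, q: float) -> float:
        """p_in - p_out at steady flow q: q (Z + R_w)."""
        return q * (self.Z + self.R_w)


@dataclass(frozen=True)
class CoronaryBed:
    """Serial microvascular ladder with an intramyocardial-pressure port.

    ``pim_scale`` weights the left-ventricular p_im applied to the three
    capacitors: 1 for LAD/LCx beds; RCA beds supply the left and right
    ventricle in a 0.4 ratio and the right ventricular p_im is 0.2 of the
    left, giving 0.4 + 0.6*0.2 = 0.52.
    """

    R_t: float
    pim_scale: float = 1.0
    hyperemia: float = 1.0       # divides the two myocardial resistances
    C_art: float = C_ART / N_TERMINALS
    C_myo: float = C_MYO / N_TERMINALS
    C_ven: float = C_VEN / N_TERMINALS
    p_out: float = VENOUS_PRESSURE

    def __post_init__(self) -> None:
        if self.R_t <= 0:
            raise ValueError("total resistance must be positive")
        if self.hyperemia < 1.0:
            raise ValueError("hyperaemia factor must be >= 1")

    @property
    def R_art(self) -> float:
        return R_SPLIT["art"] * self.R_t

    @property
    def R_myo1(self) -> float:
        return R_SPLIT["myo1"] * self.R_t / self.hyperemia

    @property
    def R_myo2(self) -> float:
        return R_SPLIT["myo2"] * self.R_t / self.hyperemia

    @property
    def R_ven(self) -> float:
        return R_SPLIT["ven"] * self.R_t

    @property
    def R_total(self) -> float:
        return self.R_art + self.R_myo1 + self.R_myo2 + self.R_ven

    def steady_flow(self, p_in: float) -> float:
        """Series-circuit flow at constant pressures and constant p_im."""
        return (p_in - self.p_out) / self.R_total


def default_coronary_bed(pim_scale: float = 1.0, hyperemia: float = 1.0,
                         p_mean: float = 100.0 * MMHG,
                         q_per_terminal: float = 20e-6 / 60.0) -> CoronaryBed:
    """Bed with R_t from a 100 mmHg mean perfusion pressure over the venous
    level at approximately 20 mL/min per terminal branch."""
    R_t = total_terminal_resistance(p_mean, VENOUS_PRESSURE, q_per_terminal)
    return CoronaryBed(R_t=R_t, pim_scale=pim_scale, hyperemia=hyperemia)


RCA_PIM_SCALE = 0.4 + 0.6 * 0.2  # LV share + RV share at 0.2 of LV p_im
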