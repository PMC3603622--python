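"""Lumped mitral and aortic valve elements.

The mitral valve is an ideal diode: a small open resistance while the
pulmonary-venous-to-ventricle gradient is forward, a very large closed
resistance otherwise. The aortic valve additionally carries the blood column's
inertia (a resistance-inductance element); it opens on a positive
ventriculo-aortic gradient and closes when its flow becomes negative. State
switching uses the previous time step's solution so the implicit system stays
linear within a step.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ValveParams:
    """Open/closed resistances (Pa s/m^3) and aortic valve geometry."""

    R_mv_o: float = 4e6
    R_mv_c: float = 1e12
    R_av_o: float = 1.0
    R_av_c: float = 1e12
    l_av: float = 10e-3     # effective valvular length, m
    A_av: float = 679e-6    # valve cross-sectional area, m^2
    rho: float = 1050.0     # blood density, kg/m^3

    def __post_init__(self) -> None:
        if self.R_mv_c < 1e4 * self.R_mv_o:
            raise ValueError("closed mitral resistance must dominate the open one")
        if self.R_av_c < 1e4 * self.R_av_o:
            raise ValueError("closed aortic resistance must dominate the open one")
        if self.l_av <= 0 or self.A_av <= 0 or self.rho <= 0:
            raise ValueError("valve geometry and blood density must be positive")

    @property
    def L_av(self) -> float:
        """Aortic valve inertance rho*l_av/A_av (Pa s^2/m^3)."""
        return self.rho * self.l_av / self.A_av


def avs_params(base: ValveParams | None = None) -> ValveParams:
    """Aortic-valve-stenosis variant: open resistance raised to 3e7 Pa s/m^3."""
    base = base or ValveParams()
    return ValveParams(R_mv_o=base.R_mv_o, R_mv_c=base.R_mv_c,
                       R_av_o=3e7, R_av_c=base.R_av_c,
                       l_av=base.l_av, A_av=base.A_av, rho=base.rho)


def mitral_resistance(dp_mv: float, p: ValveParams) -> float:
    """Diode resistance for a given transvalvular gradient."""
    return p.R_mv_o if dp_mv >= 0.0 else p.R_mv_c


def mitral_flow(dp_mv: float, p: ValveParams) -> float:
    """Ohm's-law mitral flow with the diode resistance."""
    return dp_mv / mitral_resistance(dp_mv, p)


def aortic_resistance(open_: bool, p: ValveParams) -> float:
    return p.R_av_o if open_ else p.R_av_c


def aortic_valve_residual(Q_av: float, dp_av: float, dQdt: float,
                          p: ValveParams, open_: bool = True) -> float:
    """Residual of dp_av = L_av dQ/dt + R_av Q for the current valve state."""
    return p.L_av * dQdt + aortic_resistance(open_, p) * Q_av - dp_av


def next_aortic_state(open_: bool, p_lv: float, p_ao: float, Q_av: float) -> bool:
    """Open on a positive pressure gradient, close when the flow turns negative."""
    if open_:
        return Q_av >= 0.0
    return p_lv > p_ao
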