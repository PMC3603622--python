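"""Single-fiber left-ventricular contraction model.

The left ventricle is idealised as a thick-walled sphere of incompressible
myocardium. All myofibers are lumped into a single representative fiber whose
stretch follows the cavity volume; cavity pressure follows from the fiber and
radial tissue stresses through a force balance over the wall. The same
representative mid-wall shell provides the intramyocardial pressure ``p_im``
that loads the coronary microvascular capacitors (the "intramyocardial pump"
mechanism behind systolic impediment of coronary inflow).

Active fiber stress is the product of a contractility scale and three
phenomenological factors: a length dependence ``g1``, an activation-time
dependence ``g2`` and a hyperbolic (Hill-type) shortening-velocity dependence
``g3``. Passive fiber and radial stresses are exponential in the respective
stretches and engage on opposite sides of the reference sarcomere length.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

_log = logging.getLogger(__name__)

MMHG = 133.322  # Pa per mmHg


class InvalidStateError(ValueError):
    """Raised when a physically impossible heart state is requested."""


@dataclass(frozen=True)
class HeartParams:
    """Parameters of the single-fiber ventricle.

    Volumes in m^3, lengths in m, stresses in Pa, times in s. Defaults are the
    healthy baseline; ``lvh`` variants are produced by :func:`lvh_params`.
    """

    V_lv0: float = 60e-6       # cavity volume at zero transmural pressure
    V_w: float = 200e-6        # wall volume
    l_s0: float = 1.9e-6       # sarcomere length at V_lv0
    l_sa0: float = 1.5e-6      # sarcomere length below which active stress is zero
    c: float = 1.0             # contractility (dimensionless)
    sigma_a0: float = 90e3     # active stress scale
    c_a: float = 2.4e6         # active length-curvature, 1/m
    t_r: float = 75e-3         # activation rise time constant
    t_d: float = 75e-3         # activation decay time constant
    t_max: float = 0.4         # activation duration
    v_s0: float = 10e-6        # unloaded shortening velocity, m/s
    c_v: float = 1.0           # velocity curvature
    sigma_p0: float = 0.9e3    # passive fiber stress scale
    c_p: float = 12.0          # passive fiber curvature
    sigma_r0: float = 0.2e3    # passive radial stress scale
    c_r: float = 9.0           # passive radial curvature
    T: float = 0.875           # heart period

    def __post_init__(self) -> None:
        for name in ("V_lv0", "V_w", "l_s0", "l_sa0", "sigma_a0",
                     "sigma_p0", "sigma_r0", "T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.t_max < self.T:
            raise ValueError("activation duration t_max must be shorter than the period T")
        if not self.l_sa0 < self.l_s0:
            raise ValueError("l_sa0 must be below the reference sarcomere length l_s0")


def lvh_params(base: HeartParams | None = None) -> HeartParams:
    """Hypertrophic ventricle used pre-AVR: V_w = 250 mL, contractility 1.4."""
    base = base or HeartParams()
    return replace(base, V_w=250e-6, c=1.4)


@dataclass
class HeartState:
    """Instantaneous ventricular state (volumes m^3, pressures Pa)."""

    V_lv: float
    l_s: float
    v_s: float = 0.0
    t_a: float = 0.0
    p_lv: float = 0.0
    p_im: float = 0.0


def fiber_stretch(V_lv: float, p: HeartParams) -> tuple[float, float, float]:
    """Fiber stretch, radial stretch and sarcomere length at the mid-wall shell.

    The representative shell encloses ``V_lv + V_w/3``; incompressibility gives
    ``lambda_r = lambda_f**-2``.
    """
    if V_lv <= 0:
        raise InvalidStateError(f"non-positive cavity volume {V_lv!r}")
    lam_f = ((V_lv + p.V_w / 3.0) / (p.V_lv0 + p.V_w / 3.0)) ** (1.0 / 3.0)
    return lam_f, lam_f ** -2, lam_f * p.l_s0


def g1_length(l_s: float, p: HeartParams) -> float:
    """Active stress-length factor; fibers only bear tension."""
    if l_s <= p.l_sa0:
        return 0.0
    return p.sigma_a0 * math.tanh(p.c_a * (l_s - p.l_sa0)) ** 2


def g2_activation(t_a: float, p: HeartParams) -> float:
    """Activation twitch: zero outside [0, t_max), tanh^2 rise times tanh^2 decay."""
    if t_a < 0.0 or t_a >= p.t_max:
        return 0.0
    return (math.tanh(t_a / p.t_r) ** 2
            * math.tanh((p.t_max - t_a) / p.t_d) ** 2)


def g3_velocity(v_s: float, p: HeartParams) -> float:
    """Hyperbolic force-velocity factor, 1 at isometry, 0 at v_s0.

    Inputs at or beyond the pole ``-v_s0/c_v`` are clamped just short of it
    (with a logged warning); the pole corresponds to unphysically fast
    lengthening.
    """
    pole = -p.v_s0 / p.c_v
    if v_s <= pole:
        _log.warning("g3 input %.3e at/beyond pole %.3e; clamped", v_s, pole)
        v_s = 0.99 * pole
    return (p.v_s0 - v_s) / (p.v_s0 + p.c_v * v_s)


def active_stress(l_s: float, v_s: float, t_a: float, p: HeartParams) -> float:
    """sigma_a = c * g1(l_s) * g2(t_a) * g3(v_s)."""
    return p.c * g1_length(l_s, p) * g2_activation(t_a, p) * g3_velocity(v_s, p)


def passive_stresses(lam_f: float, lam_r: float, p: HeartParams) -> tuple[float, float]:
    """Passive fiber and radial stresses.

    The fiber branch engages in extension (l_s > l_s0 i.e. lam_f > 1), the
    radial branch in compression of the fiber direction (l_s < l_s0).
    """
    if lam_f <= 0 or lam_r <= 0:
        raise InvalidStateError("stretches must be positive")
    sig_p = p.sigma_p0 * math.expm1(p.c_p * (lam_f - 1.0)) if lam_f > 1.0 else 0.0
    sig_r = p.sigma_r0 * math.expm1(p.c_r * (lam_r - 1.0)) if lam_f < 1.0 else 0.0
    return sig_p, sig_r


def lv_pressure(sigma_f: float, sigma_r_bar: float, V_lv: float, p: HeartParams) -> float:
    """Cavity pressure from the thick-walled-sphere force balance."""
    if V_lv <= 0:
        raise InvalidStateError(f"non-positive cavity volume {V_lv!r}")
    return (sigma_f - 2.0 * sigma_r_bar) / 3.0 * math.log1p(p.V_w / V_lv)


def shell_radii(V_lv: float, p: HeartParams) -> tuple[float, float, float]:
    """Inner, outer and representative (one third of the wall) sphere radii."""
    if V_lv <= 0:
        raise InvalidStateError(f"non-positive cavity volume {V_lv!r}")
    cbrt = lambda v: (3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0)
    return cbrt(V_lv), cbrt(V_lv + p.V_w), cbrt(V_lv + p.V_w / 3.0)


def intramyocardial_pressure(sigma_r_bar: float, p_lv: float, V_lv: float,
                             p: HeartParams) -> float:
    """Representative intramyocardial pressure at the mid-wall shell.

    ``p_im`` interpolates linearly between cavity pressure at the endocardium
    and zero at the epicardium, plus the radial tissue stress at the shell.
    """
    r_i, r_o, r_bar = shell_radii(V_lv, p)
    return sigma_r_bar + (r_o - r_bar) / (r_o - r_i) * p_lv


def evaluate_pressures(V_lv: float, v_s: float, t_a: float,
                       p: HeartParams) -> tuple[float, float, float]:
    """(p_lv, p_im, sigma_r_bar) for a given volume/velocity/activation state."""
    lam_f, lam_r, l_s = fiber_stretch(V_lv, p)
    sig_p, sig_r = passive_stresses(lam_f, lam_r, p)
    sig_f = sig_p + active_stress(l_s, v_s, t_a, p)
    plv = lv_pressure(sig_f, sig_r, V_lv, p)
    return plv, intramyocardial_pressure(sig_r, plv, V_lv, p), sig_r


def dls_dV(V_lv: float, p: HeartParams) -> float:
    """d l_s / d V_lv, used to map volume rate to sarcomere shortening velocity."""
    lam_f, _, _ = fiber_stretch(V_lv, p)
    return p.l_s0 * lam_f / (3.0 * (V_lv + p.V_w / 3.0))


def pressure_partials(V_lv: float, v_s: float, t_a: float, p: HeartParams,
                      dV: float = 1e-8, dv: float = 1e-8) -> tuple[float, float]:
    """Numerical (d p_lv/d V, d p_lv/d v_s) about a state; used by the implicit solver."""
    f = lambda V, v: evaluate_pressures(V, v, t_a, p)[0]
    dpdV = (f(V_lv + dV, v_s) - f(V_lv - dV, v_s)) / (2.0 * dV)
    dpdv = (f(V_lv, v_s + dv) - f(V_lv, v_s - dv)) / (2.0 * dv)
    return dpdV, dpdv


def advance_ventricle(state: HeartState, Q_mv: float, Q_av: float, dt: float,
                      p: HeartParams) -> HeartState:
    """One explicit volume-balance update of the ventricle (standalone use).

    The coupled simulator embeds these same relations implicitly; this helper
    advances an isolated ventricle for testing and exploration. ``v_s`` is the
    first-order backward difference of the sarcomere length.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    V_new = state.V_lv + dt * (Q_mv - Q_av)
    if V_new <= 0:
        raise InvalidStateError("cavity volume driven non-positive")
    _, _, l_s_new = fiber_stretch(V_new, p)
    v_s = -(l_s_new - state.l_s) / dt
    t_a = (state.t_a + dt) % p.T
    plv, pim, _ = evaluate_pressures(V_new, v_s, t_a, p)
    return HeartState(V_lv=V_new, l_s=l_s_new, v_s=v_s, t_a=t_a, p_lv=plv, p_im=pim)
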