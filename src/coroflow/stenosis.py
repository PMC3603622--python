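"""Semi-empirical stenosis element for axisymmetric narrowings.

One-dimensional theory breaks down where the cross-section changes abruptly,
so a stenotic portion of a vessel is replaced by a lumped element whose
pressure drop combines a viscous (Poiseuille-like) term, a turbulent
expansion-loss term quadratic in flow, an unsteady inertial term, and a small
mean-flow correction::

    dp_s = Kv(alpha) Rst Q + rho Kt/(2 A0^2) (A0/As - 1)^2 |Q| Q
           + Ku Lu dQ/dt + Kc(alpha) Rst Qbar

with empirical constants Kv = 1 + 0.053 (As/A0) alpha, Kt = 0.95, Ku = 1.2,
Kc = 0.0018 alpha^2, calibrated against axisymmetric finite-element
simulations of oscillatory stenotic flow. Assuming the drop develops linearly
over the stenosis length gives the differential form embedded in the 1D
network (see :meth:`StenosisSpec.momentum_coefficients`). The element itself
is rigid (zero compliance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np


def stenosis_constants(alpha: float, area_ratio: float) -> tuple[float, float, float, float]:
    """(Kv, Kt, Ku, Kc) for Womersley number alpha and throat/proximal area ratio."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if not 0.0 < area_ratio <= 1.0:
        raise ValueError("area ratio must lie in (0, 1]")
    K_v = 1.0 + 0.053 * area_ratio * alpha
    K_c = 0.0018 * alpha ** 2
    return K_v, 0.95, 1.2, K_c


@dataclass
class StenosisSpec:
    """Axisymmetric stenosis: geometry plus derived resistance and inertance.

    ``diameter_reduction`` is the percentage reduction of diameter at the
    throat (50 -> a_s = 0.5 a_0). The default throat profile is a uniform
    cylinder over the full length; an arbitrary profile a_s(z) may be supplied
    through ``profile``.
    """

    length: float                   # stenosis length L_s, m
    a0: float                       # proximal vessel radius, m
    diameter_reduction: float       # percent
    profile: Callable[[np.ndarray], np.ndarray] | None = None
    a_s: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.diameter_reduction < 100.0:
            raise ValueError("diameter reduction must be in (0, 100)%")
        if self.length <= 0 or self.a0 <= 0:
            raise ValueError("length and proximal radius must be positive")
        self.a_s = self.a0 * (1.0 - self.diameter_reduction / 100.0)

    @property
    def A0(self) -> float:
        return math.pi * self.a0 ** 2

    @property
    def As(self) -> float:
        return math.pi * self.a_s ** 2

    def throat_radius(self, z: np.ndarray) -> np.ndarray:
        if self.profile is not None:
            return np.asarray(self.profile(z), dtype=float)
        return np.full_like(np.asarray(z, dtype=float), self.a_s)

    def resistance_inertance(self, eta: float, rho: float,
                             n_quad: int = 101) -> tuple[float, float]:
        """(Rst, Lu): viscous resistance and inertance integrals over the throat."""
        z = np.linspace(0.0, self.length, n_quad)
        a_z = self.throat_radius(z)
        if np.any(a_z <= 0):
            raise ValueError("throat radius must stay positive")
        Rst = 8.0 * eta / (math.pi * self.a0 ** 4) * np.trapezoid(
            (self.a0 / a_z) ** 4, z)
        Lu = rho / (math.pi * self.a0 ** 2) * np.trapezoid((self.a0 / a_z) ** 2, z)
        return float(Rst), float(Lu)

    def momentum_coefficients(self, alpha: float, eta: float, rho: float
                              ) -> tuple[float, float, float, float]:
        """Coefficients (c_visc, c_turb, c_press, c_mean) of the differential form

        dQ/dt + c_visc Q + c_turb |Q| Q + c_press * L_s * dp/dz + c_mean Qbar = 0

        where dp/dz is approximated by the end-to-end drop over L_s.
        """
        Rst, Lu = self.resistance_inertance(eta, rho)
        K_v, K_t, K_u, K_c = stenosis_constants(alpha, self.As / self.A0)
        c_visc = K_v * Rst / (K_u * Lu)
        c_turb = rho * K_t / (2.0 * self.A0 ** 2 * K_u * Lu) * (self.A0 / self.As - 1.0) ** 2
        c_press = 1.0 / (K_u * Lu)        # multiplies (p_dist - p_prox)
        c_mean = K_c * Rst / (K_u * Lu)
        return c_visc, c_turb, c_press, c_mean

    def steady_pressure_drop(self, Q: float, alpha: float, eta: float, rho: float,
                             Q_mean: float | None = None) -> float:
        """Quasi-steady dp_s(Q) (dQ/dt = 0); Q_mean defaults to Q."""
        Rst, _ = self.resistance_inertance(eta, rho)
        K_v, K_t, _, K_c = stenosis_constants(alpha, self.As / self.A0)
        Qb = Q if Q_mean is None else Q_mean
        return (K_v * Rst * Q
                + rho * K_t / (2.0 * self.A0 ** 2) * (self.A0 / self.As - 1.0) ** 2 * abs(Q) * Q
                + K_c * Rst * Qb)
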