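"""1D wave propagation: segments, velocity-profile closure, wall shear.

Mass and momentum balances on each discretised arterial segment::

    dA/dt + dQ/dz + psi = 0
    dQ/dt + d/dz(delta Q^2/A) + (A/rho) dp/dz
        = A f_z + (2 pi a / rho) tau_w + (eta/rho) d2Q/dz2

with ``dA/dt = C(p) dp/dt`` through the wall law, and an approximate
velocity profile (inertia-dominated core of relative radius ``zeta_c``
inside a viscous Stokes layer) closing the wall shear stress ``tau_w`` and
the convective-profile factor ``delta``. The closure depends on the
Womersley number evaluated at the heart frequency only, fixed per segment.

Substituting the closure into the momentum balance merges the two dp/dz
contributions; for steady flow at small Womersley number the scheme reduces
exactly to Poiseuille's law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

ELEMENT_SIZE = 2.5e-3  # nominal non-overlapping element length, m


def womersley_alpha(a: float, f: float, rho: float, eta: float) -> float:
    """alpha = a sqrt(2 pi rho f / eta)."""
    if min(a, f, rho, eta) <= 0:
        raise ValueError("all arguments must be positive")
    return a * math.sqrt(2.0 * math.pi * rho * f / eta)


def core_fraction(alpha: float) -> float:
    """zeta_c = (max[0, 1 - 2/alpha])^2, the inertial-core area fraction."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if alpha == 0:
        return 0.0
    return max(0.0, 1.0 - 2.0 / alpha) ** 2


def convective_delta(zeta_c: float) -> float:
    """Profile factor of the convective term; 2 at zeta_c = 0, -> 1 as zeta_c -> 1."""
    if not 0.0 <= zeta_c < 1.0:
        raise ValueError("zeta_c must lie in [0, 1)")
    if zeta_c == 0.0:
        return 2.0
    if zeta_c > 0.9999:
        return 1.0
    return (2.0 - 2.0 * zeta_c * (1.0 - math.log(zeta_c))) / (1.0 - zeta_c) ** 2


def wall_shear(Q, A, dp_dz, a, zeta_c, eta):
    """tau_w = -2 eta /((1-zeta_c) a) * Q/A + (a/4)(1-zeta_c) dp/dz."""
    return (-2.0 * eta / ((1.0 - zeta_c) * a) * (Q / A)
            + 0.25 * a * (1.0 - zeta_c) * dp_dz)


@dataclass(frozen=True)
class ProfileClosure:
    """Velocity-profile parameters of one segment (fixed over a run)."""

    alpha: float
    zeta_c: float = field(init=False)
    delta: float = field(init=False)

    def __post_init__(self) -> None:
        zc = core_fraction(self.alpha)
        object.__setattr__(self, "zeta_c", zc)
        object.__setattr__(self, "delta", convective_delta(zc))


@dataclass
class VesselSegment:
    """Geometry and wall law of one 1D arterial segment.

    Radii are the physiological (13.3 kPa) values; a linear taper between the
    proximal and distal radius is assumed. ``wall`` is any object exposing
    ``compliance(p)`` and ``area(p)`` (see :mod:`coroflow.wall`).
    """

    name: str
    length: float
    r_prox: float
    r_dist: float
    h: float
    wall_kind: str = "linear"        # 'linear' | 'coronary' | 'linear_stiff'
    terminal: str | None = None      # None | 'windkessel' | 'coronary_bed'
    dz: float = ELEMENT_SIZE

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"segment {self.name}: non-positive length")
        if min(self.r_prox, self.r_dist, self.h) <= 0:
            raise ValueError(f"segment {self.name}: non-positive geometry")

    @property
    def n_elements(self) -> int:
        return max(1, round(self.length / self.dz))

    def node_radii(self) -> np.ndarray:
        """Physiological radius at each of the n_elements+1 local nodes."""
        return np.linspace(self.r_prox, self.r_dist, self.n_elements + 1)

    def closure(self, f: float, rho: float, eta: float) -> ProfileClosure:
        """Profile closure at the segment's mean physiological radius."""
        a = 0.5 * (self.r_prox + self.r_dist)
        return ProfileClosure(alpha=womersley_alpha(a, f, rho, eta))
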