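"""Arterial wall constitutive laws: pressure-dependent compliance C(p) = dA/dp.

Three laws are provided.

* :class:`CoronaryWallLaw` -- a Langewouters-type Lorentzian compliance whose
  four parameters (C_0, C_1, p_m, p_w) are polynomial functions of the vessel
  radius and the thickness-to-radius ratio kappa = h_p/a_p, pre-fitted against
  a microstructural two-fiber wall model. Used for all coronary segments.
* :class:`LinearWallLaw` -- constant compliance of a thin incompressible
  linear-elastic tube; used for the systemic arteries (E = 0.4 MPa) and as the
  comparison law for the coronary tree (E = 1.5 MPa).
* :class:`TwoFiberWallLaw` -- the thick-walled two-fiber (helically wound
  collagen in a neo-Hookean matrix) model itself, solved by numerical
  integration. It is slow and serves as an independent oracle for validating
  the Lorentzian surrogate, not as a simulation wall law.

All laws anchor the cross-sectional area at the physiological load
A(p = 13.3 kPa) = A_p = pi a_p^2, where a_p and h_p are the radius and wall
thickness measured at that pressure.

Unit convention of the Lorentzian amplitudes. The polynomial coefficient
tables are printed with an ambiguous area prefactor; here the amplitudes are
scaled by A_p relative to the reference lumen pi mm^2 (the centre of the
surrogate's fitting range), with C_1,1 = 1.09e-9 m^2/Pa and
C_0,1 = 284e-13 m^2/Pa. This reading was selected empirically as the one that
tracks the two-fiber oracle's compliance curve (amplitude within ~11%, peak
position and width confirmed by an unconstrained refit) and yields coronary
pulse-wave speeds near 10 m/s at physiological pressure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

P_PHYS = 13.3e3  # anchoring pressure, Pa

A_REF = math.pi * 1e-6  # reference lumen area (1 mm radius), m^2

#: Polynomial coefficient tables for the Langewouters surrogate.
#: brackets: f(kappa) = 1 + c2*kappa^2 + c3*kappa; offsets: c1 + c2/kappa + c3*kappa.
LANGEWOUTERS_COEFFS = {
    "C0": (284e-13, 12.1, -3.59),   # amplitude (m^2/Pa at A_p = pi mm^2), kappa^2, kappa
    "C1": (1.09e-9, 34.7, -9.85),
    "pm": (646.0, -17.0, 15.9e3),   # Pa
    "pw": (708.0, -14.8, 12.9e3),   # Pa
}


class WallCollapseError(RuntimeError):
    """Area driven non-positive: outside the model's validity."""


def langewouters_coeffs(a_p: float, h_p: float) -> tuple[float, float, float, float]:
    """(C_0, C_1, p_m, p_w) of the Lorentzian compliance for a coronary vessel.

    Valid for kappa = h_p/a_p in (0.05, 0.15), the surrogate's fitting range;
    a warning is issued outside it.
    """
    if a_p <= 0 or h_p <= 0:
        raise ValueError("invalid geometry: radius and thickness must be positive")
    kappa = h_p / a_p
    if not 0.05 < kappa < 0.15:
        warnings.warn(f"kappa={kappa:.3f} outside the fitted range (0.05, 0.15)",
                      stacklevel=2)
    A_p = math.pi * a_p ** 2
    c0_1, c0_2, c0_3 = LANGEWOUTERS_COEFFS["C0"]
    c1_1, c1_2, c1_3 = LANGEWOUTERS_COEFFS["C1"]
    C0 = (A_p / A_REF) * c0_1 * (1.0 + c0_2 * kappa ** 2 + c0_3 * kappa)
    C1 = (A_p / A_REF) * c1_1 * (1.0 + c1_2 * kappa ** 2 + c1_3 * kappa)
    pm_1, pm_2, pm_3 = LANGEWOUTERS_COEFFS["pm"]
    pw_1, pw_2, pw_3 = LANGEWOUTERS_COEFFS["pw"]
    p_m = pm_1 + pm_2 / kappa + pm_3 * kappa
    p_w = pw_1 + pw_2 / kappa + pw_3 * kappa
    return C0, C1, p_m, p_w


@dataclass(frozen=True)
class CoronaryWallLaw:
    """Langewouters-type compliance law for a coronary segment."""

    a_p: float
    h_p: float
    C0: float = field(init=False)
    C1: float = field(init=False)
    p_m: float = field(init=False)
    p_w: float = field(init=False)

    def __post_init__(self) -> None:
        C0, C1, p_m, p_w = langewouters_coeffs(self.a_p, self.h_p)
        for name, val in (("C0", C0), ("C1", C1), ("p_m", p_m), ("p_w", p_w)):
            object.__setattr__(self, name, val)
        if p_w <= 0 or C0 <= 0 or C1 <= 0:
            raise ValueError("degenerate Langewouters parameters")

    @property
    def kappa(self) -> float:
        return self.h_p / self.a_p

    @property
    def A_p(self) -> float:
        return math.pi * self.a_p ** 2

    def compliance(self, p):
        """C(p) = C_0 + C_1 / (1 + ((p - p_m)/p_w)^2); maximal at p = p_m."""
        return self.C0 + self.C1 / (1.0 + ((p - self.p_m) / self.p_w) ** 2)

    def area(self, p):
        """Closed-form integral of C(p) anchored at A(P_PHYS) = A_p."""
        atan = np.arctan
        integ = (self.C0 * (p - P_PHYS)
                 + self.C1 * self.p_w * (atan((p - self.p_m) / self.p_w)
                                         - atan((P_PHYS - self.p_m) / self.p_w)))
        A = self.A_p + integ
        if np.any(np.asarray(A) <= 0):
            raise WallCollapseError("coronary lumen area driven non-positive")
        return A


@dataclass(frozen=True)
class LinearWallLaw:
    """Thin incompressible linear-elastic tube: pressure-independent compliance."""

    a_p: float
    h_p: float
    E: float = 0.4e6
    mu: float = 0.5

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("Young's modulus must be positive")

    @property
    def A_p(self) -> float:
        return math.pi * self.a_p ** 2

    def compliance(self, p=None):
        """C = 2 pi (1 - mu^2) a_p^3 / (h_p E)."""
        c = 2.0 * math.pi * (1.0 - self.mu ** 2) * self.a_p ** 3 / (self.h_p * self.E)
        if p is None:
            return c
        return np.full_like(np.asarray(p, dtype=float), c)

    def area(self, p):
        A = self.A_p + self.compliance() * (np.asarray(p, dtype=float) - P_PHYS)
        if np.any(A <= 0):
            raise WallCollapseError("lumen area driven non-positive")
        return A


def linear_compliance(law: LinearWallLaw) -> float:
    return law.compliance()


def coronary_compliance(p, law: CoronaryWallLaw):
    return law.compliance(p)


def area_from_pressure(p, law):
    return law.area(p)


# --------------------------------------------------------------------------
# Two-fiber thick-wall oracle
# --------------------------------------------------------------------------

@dataclass
class TwoFiberWallLaw:
    """Thick-walled two-fiber coronary wall model (validation oracle).

    The wall is a neo-Hookean matrix (shear modulus ``G``) reinforced by two
    helical collagen families at +/- beta to the circumference; fibers bear
    tension only, with an exponentially stiffening stress-stretch law
    (``k1``, ``k2``). The unloaded configuration has an opening angle; the
    sector parameter ``k`` and the axial stretch ``lam_z`` are calibrated by
    two rules evaluated at physiological load (13.3 kPa):

    1. the circumferential stress is uniform across the wall, and
    2. the deformed mid-wall fiber angle equals ``beta_phys``.

    Median coronary parameters: G = 19.3 kPa, k1 = 2.01 kPa, k2 = 5.10,
    beta0 = 34.6 deg, beta_phys = 36.4 deg.
    """

    a_p: float
    h_p: float
    G: float = 19.3e3
    k1: float = 2.01e3
    k2: float = 5.10
    beta0_deg: float = 34.6
    beta_phys_deg: float = 36.4
    n_quad: int = 81
    # calibrated reference geometry
    R_i: float = field(init=False, default=0.0)
    R_o: float = field(init=False, default=0.0)
    k: float = field(init=False, default=0.0)
    lam_z: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.G <= 0:
            raise ValueError("elastic moduli must be positive")
        self._calibrate()

    # -- kinematics and stress -------------------------------------------
    def _fiber_stress(self, lf2):
        return np.where(lf2 >= 1.0,
                        self.k1 * lf2 * (lf2 - 1.0) * np.exp(self.k2 * (lf2 - 1.0) ** 2),
                        0.0)

    def _wall_state(self, r_i: float, R_i: float, R_o: float, k: float, lam_z: float):
        """Radial profiles of the deformed wall for inner radius r_i."""
        R = np.linspace(R_i, R_o, self.n_quad)
        r = np.sqrt(r_i ** 2 + (R ** 2 - R_i ** 2) / (k * lam_z))
        lam_t = k * r / R
        lam_r = 1.0 / (lam_t * lam_z)
        b0 = math.radians(self.beta0_deg)
        lf2 = lam_t ** 2 * math.cos(b0) ** 2 + lam_z ** 2 * math.sin(b0) ** 2
        beta = np.arctan2(lam_z * math.sin(b0), lam_t * math.cos(b0))
        # circumferential-radial Cauchy stress difference (two fiber families)
        dsig = (self.G * (lam_t ** 2 - lam_r ** 2)
                + 2.0 * self._fiber_stress(lf2) * np.cos(beta) ** 2)
        return r, lam_t, beta, dsig

    def _pressure(self, r_i: float, R_i=None, R_o=None, k=None, lam_z=None) -> float:
        """Luminal pressure balancing the wall at deformed inner radius r_i."""
        R_i = self.R_i if R_i is None else R_i
        R_o = self.R_o if R_o is None else R_o
        k = self.k if k is None else k
        lam_z = self.lam_z if lam_z is None else lam_z
        r, _, _, dsig = self._wall_state(r_i, R_i, R_o, k, lam_z)
        return float(np.trapezoid(dsig / r, r))

    def _calibrate(self) -> None:
        r_ip, r_op = self.a_p, self.a_p + self.h_p
        b0 = math.radians(self.beta0_deg)
        bp = math.radians(self.beta_phys_deg)
        lam_t_target = lambda lam_z: lam_z * math.tan(b0) / math.tan(bp)

        def residuals(x):
            R_i, k, lam_z = x
            R_o = math.sqrt(R_i ** 2 + k * lam_z * (r_op ** 2 - r_ip ** 2))
            r, lam_t, _, dsig = self._wall_state(r_ip, R_i, R_o, k, lam_z)
            integrand = dsig / r
            p = np.trapezoid(integrand, r)
            # sigma_theta profile: sigma_rr(r) + dsig(r), sigma_rr from equilibrium
            srr = -p + np.concatenate(
                [[0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * np.diff(r))])
            sth = srr + dsig
            mid = len(r) // 2
            return [(p - P_PHYS) / P_PHYS,
                    (sth[0] - sth[-1]) / max(abs(sth[0]), 1.0),
                    lam_t[mid] - lam_t_target(lam_z)]

        sol = least_squares(residuals, [self.a_p * 0.75, 1.2, 1.3],
                            bounds=([self.a_p * 0.2, 1.0, 1.0],
                                    [self.a_p * 2.0, 4.0, 2.0]))
        if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
            raise RuntimeError("two-fiber wall calibration did not converge")
        self.R_i, self.k, self.lam_z = map(float, sol.x)
        self.R_o = math.sqrt(self.R_i ** 2
                             + self.k * self.lam_z * (r_op ** 2 - r_ip ** 2))

    # -- public surface ---------------------------------------------------
    def inner_radius(self, p: float) -> float:
        """Deformed inner radius at luminal pressure p (axial stretch fixed)."""
        return brentq(lambda ri: self._pressure(ri) - p,
                      self.R_i * 0.2, self.a_p * 3.0, xtol=1e-13)

    def pressure_radius_curve(self, pressures) -> np.ndarray:
        """Array of inner radii for an array of pressures."""
        return np.array([self.inner_radius(p) for p in np.asarray(pressures)])

    def area(self, p: float) -> float:
        return math.pi * self.inner_radius(p) ** 2

    def compliance(self, p, dp: float = 50.0):
        """dA/dp by central difference."""
        p = np.atleast_1d(np.asarray(p, dtype=float))
        out = np.array([(self.area(pi + dp) - self.area(pi - dp)) / (2 * dp)
                        for pi in p])
        return out if out.size > 1 else float(out[0])
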