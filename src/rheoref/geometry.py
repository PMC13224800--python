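"""Double wall-ring (DWR) cell geometry and analytic instrument quantities.

The DWR probe is a diamond-cross-section ring suspended at a fluid interface
inside a double-gap annular channel.  The interface is sheared in the two
annular gaps, ``[R_i, R4]`` (inner cup wall to inner contact line) and
``[R5, R_o]`` (outer contact line to outer cup wall).  This module holds the
geometry container plus the closed-form quantities that do not require a flow
solution: the area-averaged interfacial strain, the high-Boussinesq-number
interfacial drag coefficient ``g1``, the rotor-inertia sensitivity floor and
the capillary length.

All lengths are SI metres unless noted otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "G_GRAV",
    "DWRGeometry",
    "ProbeDynamics",
    "FluidPhase",
    "WATER",
    "AIR",
    "average_strain",
    "g1_coefficient",
    "inertia_limit",
    "capillary_length",
]

#: Standard gravitational acceleration (m/s^2).
G_GRAV = 9.81

_REL_TOL = 1e-9


@dataclass(frozen=True)
class DWRGeometry:
    """Radii and cross-section of the double wall-ring cell.

    Parameters
    ----------
    R_i, R_o :
        Inner and outer cup wall radii (m).
    R4, R5 :
        Inner and outer contact-line radii of the ring (m).  Their difference
        equals the horizontal diagonal of the diamond cross-section.
    diagonal :
        Diamond cross-section diagonal (m); the diamond is a square rotated by
        45 deg, so both diagonals are equal and the side is ``diagonal/sqrt(2)``.
    depth :
        Channel depth below the interface (m).
    a :
        Probe area-to-perimeter length scale (m).  Defaults to the diamond
        side length ``L``: each of the two contact lines carries a wetted strip
        of width ``L``, so area/perimeter = 2*L*P / (2*P) = L.
    """

    R_i: float = 20.0e-3
    R4: float = 23.0e-3
    R5: float = 24.0e-3
    R_o: float = 28.79e-3
    diagonal: float = 1.0e-3
    depth: float = 5.0e-3
    a: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.R_i < self.R4 < self.R5 < self.R_o):
            raise ValueError(
                f"radii must satisfy 0 < R_i < R4 < R5 < R_o, got "
                f"({self.R_i}, {self.R4}, {self.R5}, {self.R_o})"
            )
        if self.diagonal <= 0.0 or self.depth <= 0.0:
            raise ValueError("diagonal and depth must be positive")
        gap_ring = self.R5 - self.R4
        if abs(gap_ring - self.diagonal) > _REL_TOL * self.diagonal + 1e-15:
            raise ValueError(
                f"R5 - R4 = {gap_ring} must equal the diamond diagonal "
                f"{self.diagonal}"
            )
        if self.a is None:
            object.__setattr__(self, "a", self.L)
        elif self.a <= 0.0:
            raise ValueError("a must be positive")

    @property
    def L(self) -> float:
        """Diamond side length (m), ``diagonal / sqrt(2)``."""
        return self.diagonal / math.sqrt(2.0)

    @property
    def R_c(self) -> float:
        """Mid-radius of the ring cross-section (m)."""
        return 0.5 * (self.R4 + self.R5)

    def gaps(self) -> tuple[float, float]:
        """Widths of the inner and outer interfacial gaps (m)."""
        return (self.R4 - self.R_i, self.R_o - self.R5)


@dataclass(frozen=True)
class ProbeDynamics:
    """Rotor + probe inertia and high-Bo geometric drag coefficient.

    ``g1`` converts an interfacial modulus into a torque per radian of
    angular displacement (N*m per (N/m) per rad).  ``I`` is the moment of
    inertia of the rotor plus DWR assembly (kg*m^2).
    """

    I: float
    g1: float

    def __post_init__(self) -> None:
        if self.I <= 0.0 or self.g1 <= 0.0:
            raise ValueError("I and g1 must be positive")

    @classmethod
    def from_geometry(cls, I: float, geom: DWRGeometry) -> "ProbeDynamics":
        return cls(I=I, g1=g1_coefficient(geom))


@dataclass(frozen=True)
class FluidPhase:
    """Newtonian bulk phase: dynamic viscosity (Pa*s), density (kg/m^3)."""

    eta: float
    rho: float
    surface_tension: Optional[float] = None

    def __post_init__(self) -> None:
        if self.eta < 0.0:
            raise ValueError("eta must be non-negative")
        if self.rho <= 0.0:
            raise ValueError("rho must be positive")


#: Water near room temperature.
WATER = FluidPhase(eta=1.0e-3, rho=998.0, surface_tension=72.0e-3)
#: Air near room temperature.
AIR = FluidPhase(eta=1.8e-5, rho=1.2)


def _check_gaps(geom: DWRGeometry) -> None:
    g_in, g_out = geom.gaps()
    if g_in <= _REL_TOL * geom.R4 or g_out <= _REL_TOL * geom.R_o:
        raise ValueError("zero-width annular gap (R4 ~ R_i or R5 ~ R_o)")


def average_strain(theta0: float, geom: DWRGeometry) -> float:
    """Area-averaged interfacial shear strain for angular amplitude ``theta0``.

    In the limit of interface-dominated drag the interfacial velocity in each
    gap follows the annular-Couette profile ``u = C1*r + C2/r`` and the local
    shear strain of the displacement field is ``gamma(r) = r d(u_disp/r)/dr =
    -2 C2 theta0 / r^2``.  Averaging ``gamma(r)`` over the annular area of the
    two gaps gives

    ``gamma = 4 theta0 [Ri^2 R4^2 ln(R4/Ri)/(R4^2-Ri^2)
                        + R5^2 Ro^2 ln(Ro/R5)/(Ro^2-R5^2)]
              / [(R4^2-Ri^2) + (Ro^2-R5^2)]``

    which is linear in ``theta0``.
    """
    if theta0 < 0.0:
        raise ValueError("theta0 must be non-negative")
    _check_gaps(geom)
    Ri2, R42 = geom.R_i**2, geom.R4**2
    R52, Ro2 = geom.R5**2, geom.R_o**2
    A_in = R42 - Ri2
    A_out = Ro2 - R52
    num = (
        Ri2 * R42 * math.log(geom.R4 / geom.R_i) / A_in
        + R52 * Ro2 * math.log(geom.R_o / geom.R5) / A_out
    )
    return 4.0 * theta0 * num / (A_in + A_out)


def g1_coefficient(geom: DWRGeometry) -> float:
    """High-Bo geometric drag coefficient ``g1`` (m^2 * m).

    Closed form from the annular-Couette torque exerted on the ring by a
    purely interfacial stress in both gaps:

    ``g1 = 4 pi [ Ri^2 R4^2 / (R4^2 - Ri^2) + R5^2 Ro^2 / (Ro^2 - R5^2) ]``

    so that the interfacial drag torque in the interface-dominated limit is
    ``T_i = g1 * G* * theta0``.  Validated against the finite-difference flow
    solver in the elastic-plate limit.
    """
    _check_gaps(geom)
    Ri2, R42 = geom.R_i**2, geom.R4**2
    R52, Ro2 = geom.R5**2, geom.R_o**2
    return 4.0 * math.pi * (
        Ri2 * R42 / (R42 - Ri2) + R52 * Ro2 / (Ro2 - R52)
    )


def inertia_limit(I: float, omega: float, g1: float) -> float:
    """Inertia-limited modulus floor ``G_lim = I omega^2 / g1`` (N/m).

    Below this value the rotor+probe inertia dominates the torque balance and
    interfacial moduli cannot be resolved; it is the dotted "inertia" line in
    sensitivity plots and scales as ``omega^2``.
    """
    if I <= 0.0 or g1 <= 0.0 or omega < 0.0:
        raise ValueError("require I > 0, g1 > 0 and omega >= 0")
    return I * omega**2 / g1


def capillary_length(sigma: float, rho: float) -> float:
    """Capillary length ``sqrt(sigma / (rho g))`` (m).

    ~2.7 mm for a clean air/water interface; the DWR gap widths are chosen
    slightly larger than this so meniscus effects stay confined.
    """
    if sigma <= 0.0 or rho <= 0.0:
        raise ValueError("sigma and rho must be positive")
    return math.sqrt(sigma / (rho * G_GRAV))
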