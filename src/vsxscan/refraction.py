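"""Spherocylindrical prescriptions, power vectors, and objective refraction.

Clinical minus-cylinder convention throughout: a prescription is
(sphere S, cylinder C <= 0, axis in [0, 180) degrees).  The power-vector
representation (M, J0, J45) follows the standard Fourier decomposition:

    M   = S + C/2
    J0  = -(C/2) cos(2 axis)
    J45 = -(C/2) sin(2 axis)

Objective refractions are computed from normalized Zernike coefficients
c_n^m (micrometres) over a pupil of radius r (mm):

* Zernike refraction - second-order terms only:
    M = -4*sqrt(3)*c20 / r^2,  J0 = -2*sqrt(6)*c22 / r^2,
    J45 = -2*sqrt(6)*c2m2 / r^2.

* Seidel refraction - paraxial curvature matching, i.e. the r^2 content of
  the wavefront at the pupil centre, which mixes in the radially symmetric
  and (optionally) astigmatic terms of orders 4 and 6:
    M   = (-4*sqrt(3)*c20 + 12*sqrt(5)*c40 - 24*sqrt(7)*c60) / r^2
    J0  = (-2*sqrt(6)*c22 + 6*sqrt(10)*c42 - 12*sqrt(14)*c62) / r^2
    J45 = likewise with the m = -2 terms.

The factors are the rho^2 coefficients of the corresponding radial
polynomials (R_4^0 contributes -6 rho^2, R_6^0 +12 rho^2, R_4^2 -3 rho^2,
R_6^2 +6 rho^2) times the ANSI normalization constants.

The returned prescription is the correcting-lens power that nulls the
paraxial content of the wavefront (a myopic eye yields a minus sphere).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .zernike import WavefrontCoefficients

__all__ = [
    "SpherocylRx",
    "PowerVector",
    "rx_to_power_vector",
    "power_vector_to_rx",
    "zernike_refraction",
    "seidel_refraction",
]


@dataclass(frozen=True)
class SpherocylRx:
    """Spherocylindrical prescription in minus-cylinder form."""

    sphere_D: float
    cylinder_D: float = 0.0
    axis_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.cylinder_D > 1e-12:
            raise ValueError("cylinder must be <= 0 (minus-cylinder form); transpose first")

    @staticmethod
    def normalized(sphere_D: float, cylinder_D: float, axis_deg: float) -> "SpherocylRx":
        """Canonical minus-cylinder form with axis folded into [0, 180)."""
        if cylinder_D > 0:
            sphere_D = sphere_D + cylinder_D
            cylinder_D = -cylinder_D
            axis_deg = axis_deg + 90.0
        axis_deg = axis_deg % 180.0
        if abs(cylinder_D) < 1e-12:
            cylinder_D = 0.0
            axis_deg = 0.0
        return SpherocylRx(sphere_D, cylinder_D, axis_deg)

    def transposed(self) -> "SpherocylRx":
        """Plus-cylinder equivalent folded back to canonical minus form."""
        return SpherocylRx.normalized(
            self.sphere_D + self.cylinder_D, -self.cylinder_D, self.axis_deg + 90.0
        )

    def __str__(self) -> str:
        return f"{self.sphere_D:+.2f} {self.cylinder_D:+.2f} x {self.axis_deg:.1f}"

    @staticmethod
    def from_string(s: str) -> "SpherocylRx":
        """Parse an 'S C x A' or 'S/CxA' clinical string."""
        txt = s.replace("/", " ").replace("x", " ").replace("X", " ")
        parts = [p for p in txt.split() if p]
        if len(parts) == 1:
            return SpherocylRx.normalized(float(parts[0]), 0.0, 0.0)
        if len(parts) != 3:
            raise ValueError(f"cannot parse prescription {s!r}")
        return SpherocylRx.normalized(float(parts[0]), float(parts[1]), float(parts[2]))


@dataclass(frozen=True)
class PowerVector:
    """Power-vector (M, J0, J45) representation of a prescription, diopters."""

    M: float
    J0: float
    J45: float

    def as_array(self) -> np.ndarray:
        return np.array([self.M, self.J0, self.J45])

    def blur_strength(self) -> float:
        """Overall dioptric blur ``sqrt(M^2 + J0^2 + J45^2)``."""
        return math.sqrt(self.M**2 + self.J0**2 + self.J45**2)


def rx_to_power_vector(rx: SpherocylRx) -> PowerVector:
    c2 = rx.cylinder_D / 2.0
    ax = math.radians(rx.axis_deg)
    return PowerVector(
        M=rx.sphere_D + c2,
        J0=-c2 * math.cos(2 * ax),
        J45=-c2 * math.sin(2 * ax),
    )


def power_vector_to_rx(pv: PowerVector) -> SpherocylRx:
    j = math.hypot(pv.J0, pv.J45)
    cyl = -2.0 * j
    sph = pv.M - cyl / 2.0
    if j < 1e-12:
        return SpherocylRx(pv.M, 0.0, 0.0)
    axis = math.degrees(0.5 * math.atan2(pv.J45, pv.J0)) % 180.0
    return SpherocylRx(sph, cyl, axis)


_S3 = math.sqrt(3.0)
_S5 = math.sqrt(5.0)
_S6 = math.sqrt(6.0)
_S7 = math.sqrt(7.0)
_S10 = math.sqrt(10.0)
_S14 = math.sqrt(14.0)


def zernike_refraction(w: WavefrontCoefficients) -> SpherocylRx:
    """Refraction from second-order Zernike terms only."""
    r2 = w.pupil_radius_mm**2
    m = -4.0 * _S3 * w.c(2, 0) / r2
    j0 = -2.0 * _S6 * w.c(2, 2) / r2
    j45 = -2.0 * _S6 * w.c(2, -2) / r2
    return power_vector_to_rx(PowerVector(m, j0, j45))


def seidel_refraction(
    w: WavefrontCoefficients, include_astigmatic_higher: bool = True
) -> SpherocylRx:
    """Paraxial curvature-matching refraction from orders 2-6.

    ``include_astigmatic_higher`` controls whether the astigmatic chains
    (c4^±2, c6^±2) are included alongside the spherical-equivalent chain;
    the default includes them.
    """
    r2 = w.pupil_radius_mm**2
    m = (-4.0 * _S3 * w.c(2, 0) + 12.0 * _S5 * w.c(4, 0) - 24.0 * _S7 * w.c(6, 0)) / r2
    j0 = -2.0 * _S6 * w.c(2, 2) / r2
    j45 = -2.0 * _S6 * w.c(2, -2) / r2
    if include_astigmatic_higher:
        j0 += (6.0 * _S10 * w.c(4, 2) - 12.0 * _S14 * w.c(6, 2)) / r2
        j45 += (6.0 * _S10 * w.c(4, -2) - 12.0 * _S14 * w.c(6, -2)) / r2
    return power_vector_to_rx(PowerVector(m, j0, j45))
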