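"""Optical surface geometry: conic and biconic sections with optional cone bump.

All lengths are in millimetres unless noted otherwise.  The coordinate frame
is right-handed with +z pointing from the cornea toward the retina, +y
superior, and meridian angles measured in degrees counterclockwise from +x
as seen from in front of the eye.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = [
    "ConicSurface",
    "ConeParams",
    "surface_sag",
    "surface_sag_and_gradient",
    "apply_cone",
]


@dataclass
class ConeParams:
    """Gaussian anterior-elevation perturbation modelling a keratoconic cone.

    The cone protrudes forward (toward the incoming light): the perturbed sag
    is ``sag(x, y) - amplitude * exp(-((x-cx)^2 + (y-cy)^2) / (2 sigma^2))``.
    ``amplitude_um == 0`` encodes "no cone".
    """

    center_x_mm: float = 0.0
    center_y_mm: float = 0.0
    amplitude_um: float = 0.0
    sigma_mm: float = 1.5

    def __post_init__(self) -> None:
        if self.amplitude_um < 0:
            raise ValueError("cone amplitude must be >= 0")
        if self.sigma_mm <= 0:
            raise ValueError("cone sigma must be > 0")

    @property
    def amplitude_mm(self) -> float:
        return self.amplitude_um * 1e-3


@dataclass
class ConicSurface:
    """One refracting surface: a conic of revolution, optionally biconic.

    ``radius_mm`` is the signed apical radius of curvature along the meridian
    ``toric_axis_deg`` (or every meridian when the surface is rotationally
    symmetric).  ``toric_radius_mm``, when present, is the apical radius of
    the perpendicular meridian; the conic constant is shared by both
    meridians.  ``n_after`` is the refractive index of the medium that
    follows the surface, and ``thickness_mm`` the axial distance to the next
    surface.
    """

    radius_mm: float
    conic: float = 0.0
    n_after: float = 1.0
    thickness_mm: float = 0.0
    toric_radius_mm: Optional[float] = None
    toric_axis_deg: Optional[float] = None
    semi_aperture_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.radius_mm == 0:
            raise ValueError("radius_mm must be nonzero")
        if self.n_after < 1.0:
            raise ValueError("n_after must be >= 1")
        if self.thickness_mm < 0:
            raise ValueError("thickness_mm must be >= 0")
        if self.toric_radius_mm is not None and self.toric_axis_deg is None:
            self.toric_axis_deg = 0.0
        if self.toric_axis_deg is not None:
            if not (0.0 <= self.toric_axis_deg < 180.0):
                raise ValueError("toric_axis_deg must lie in [0, 180)")

    @property
    def is_toric(self) -> bool:
        return self.toric_radius_mm is not None

    @property
    def curvature(self) -> float:
        return 1.0 / self.radius_mm

    def curvatures(self) -> tuple[float, float]:
        """Apical curvatures along the axis meridian and its perpendicular."""
        c1 = 1.0 / self.radius_mm
        c2 = c1 if self.toric_radius_mm is None else 1.0 / self.toric_radius_mm
        return c1, c2

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ConicSurface":
        return cls(**d)


def _biconic_sag_grad(surface: ConicSurface, x, y, want_grad: bool):
    """Sag (and optionally in-plane gradient) of a (bi)conic surface.

    Biconic sag with shared conic constant k:

        z = (cu*u^2 + cv*v^2) / (1 + sqrt(1 - (1+k)*(cu^2*u^2 + cv^2*v^2)))

    with (u, v) the coordinates rotated into the toric axis frame.  For
    cu == cv this reduces to the standard conic section sag.
    """
    cu, cv = surface.curvatures()
    k = surface.conic
    theta = math.radians(surface.toric_axis_deg or 0.0)
    ct, st = math.cos(theta), math.sin(theta)
    u = ct * x + st * y
    v = -st * x + ct * y
    u2, v2 = u * u, v * v
    a = cu * u2 + cv * v2
    b = (1.0 + k) * (cu * cu * u2 + cv * cv * v2)
    inside = 1.0 - b
    bad = inside < 0.0
    s = np.sqrt(np.where(bad, 0.0, inside))
    denom = 1.0 + s
    z = a / denom
    z = np.where(bad, np.nan, z)
    if not want_grad:
        return z, None, None
    # d(z)/du = (a'*denom - a*denom')/denom^2, denom' = -b'/(2 s)
    with np.errstate(divide="ignore", invalid="ignore"):
        da_du = 2.0 * cu * u
        da_dv = 2.0 * cv * v
        db_du = 2.0 * (1.0 + k) * cu * cu * u
        db_dv = 2.0 * (1.0 + k) * cv * cv * v
        inv_2s = 1.0 / (2.0 * np.maximum(s, 1e-14))
        dden_du = db_du * inv_2s
        dden_dv = db_dv * inv_2s
        inv_d2 = 1.0 / (denom * denom)
        dz_du = (da_du * denom + a * dden_du) * inv_d2
        dz_dv = (da_dv * denom + a * dden_dv) * inv_d2
    dz_dx = ct * dz_du - st * dz_dv
    dz_dy = st * dz_du + ct * dz_dv
    dz_dx = np.where(bad, np.nan, dz_dx)
    dz_dy = np.where(bad, np.nan, dz_dy)
    return z, dz_dx, dz_dy


def _cone_sag_grad(cone: ConeParams, x, y, want_grad: bool):
    a = cone.amplitude_mm
    dx = x - cone.center_x_mm
    dy = y - cone.center_y_mm
    g = np.exp(-(dx * dx + dy * dy) / (2.0 * cone.sigma_mm**2))
    z = -a * g
    if not want_grad:
        return z, None, None
    f = a * g / (cone.sigma_mm**2)
    return z, f * dx, f * dy


def surface_sag(surface: ConicSurface, x, y, cone: Optional[ConeParams] = None):
    """Sag z(x, y) in mm; NaN outside the conic's domain of definition."""
    z, _, _ = _biconic_sag_grad(surface, np.asarray(x, float), np.asarray(y, float), False)
    if cone is not None and cone.amplitude_um > 0:
        zc, _, _ = _cone_sag_grad(cone, np.asarray(x, float), np.asarray(y, float), False)
        z = z + zc
    return z


def apply_cone(sag_fn, cone: ConeParams):
    """Wrap a base sag function with the Gaussian cone perturbation.

    ``sag'(x, y) = sag(x, y) - a * exp(-((x-cx)^2 + (y-cy)^2) / (2 sigma^2))``
    with the amplitude in mm; amplitude 0 is the identity."""

    def perturbed(x, y):
        z, _, _ = _cone_sag_grad(cone, np.asarray(x, float), np.asarray(y, float), False)
        return sag_fn(x, y) + z

    return perturbed


def surface_sag_and_gradient(
    surface: ConicSurface, x, y, cone: Optional[ConeParams] = None
):
    """Sag and its in-plane gradient (dz/dx, dz/dy)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z, gx, gy = _biconic_sag_grad(surface, x, y, True)
    if cone is not None and cone.amplitude_um > 0:
        zc, gcx, gcy = _cone_sag_grad(cone, x, y, True)
        z = z + zc
        gx = gx + gcx
        gy = gy + gcy
    return z, gx, gy
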