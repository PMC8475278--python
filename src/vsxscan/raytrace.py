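"""Exact sequential ray tracing from a flat incoming wavefront to the
exit-pupil optical path difference.

The trace launches a bundle of parallel rays (object at infinity on axis),
aimed so that the bundle fills the 5-mm physical pupil at the crystalline
lens front vertex, refracts it through the correction (if any) and the four
ocular surfaces, and evaluates the optical path difference of every ray
against the chief ray on the reference sphere centred on the chief ray's
retinal intersection and passing through the exit pupil.

Sign convention: ``opd_um = (OPL_chief - OPL_ray) * 1000`` so that a myopic
eye produces a positive defocus coefficient and hence a minus-sphere
objective refraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import paraxial
from .correction import CorrectionLens
from .eye import EyeBiometry, N_VITREOUS
from .geometry import ConeParams, ConicSurface, surface_sag_and_gradient

__all__ = ["pupil_samples", "trace_system", "TraceResult", "TraceError"]


class TraceError(RuntimeError):
    """Raised when a configuration cannot be traced meaningfully."""


_HEXAPOLAR_RINGS = (1, 8, 16, 24, 32, 40)  # 121 rays


def pupil_samples(n_rings: int = 5) -> np.ndarray:
    """Hexapolar sampling of the unit disk: 1 + 8 + 16 + ... rays on rings
    at radii proportional to the ring index (121 rays for 5 rings).

    The first sample is the pupil centre (chief ray)."""
    pts = [(0.0, 0.0)]
    for i in range(1, n_rings + 1):
        r = i / n_rings
        n = _HEXAPOLAR_RINGS[i] if i < len(_HEXAPOLAR_RINGS) else 8 * i
        ang = 2.0 * np.pi * np.arange(n) / n
        pts.extend(zip(r * np.cos(ang), r * np.sin(ang)))
    return np.asarray(pts)


@dataclass
class TraceResult:
    """Exit-pupil OPD samples of one trace."""

    pupil_xy_norm: np.ndarray  # achieved physical-pupil coords / pupil radius
    opd_um: np.ndarray
    valid: np.ndarray
    n_lost: int
    chief_retina_xy_mm: tuple
    exit_pupil_z_mm: float
    pupil_radius_mm: float

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "x_norm": self.pupil_xy_norm[:, 0],
                "y_norm": self.pupil_xy_norm[:, 1],
                "opd_um": self.opd_um,
                "valid": self.valid,
            }
        ).to_csv(path, index=False)


# --------------------------------------------------------------------------
# Elementary ray operations (vectorized over the bundle)


def _intersect_conic_closed(p, d, c, k):
    """Closed-form intersection with a rotationally symmetric conic
    (implicit form c*(x^2+y^2) + c*(1+k)*z^2 - 2 z = 0), local coordinates.

    Returns (t, ok)."""
    kp = 1.0 + k
    a = c * (d[:, 0] ** 2 + d[:, 1] ** 2 + kp * d[:, 2] ** 2)
    b = 2.0 * c * (
        p[:, 0] * d[:, 0] + p[:, 1] * d[:, 1] + kp * p[:, 2] * d[:, 2]
    ) - 2.0 * d[:, 2]
    cc = c * (p[:, 0] ** 2 + p[:, 1] ** 2 + kp * p[:, 2] ** 2) - 2.0 * p[:, 2]
    disc = b * b - 4.0 * a * cc
    ok = disc >= 0.0
    sq = np.sqrt(np.maximum(disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        sb = np.where(b >= 0, 1.0, -1.0)
        qq = -0.5 * (b + sb * sq)
        t1 = np.where(np.abs(a) > 1e-14, qq / np.where(np.abs(a) > 1e-14, a, 1.0), np.inf)
        t2 = np.where(np.abs(qq) > 1e-14, cc / np.where(np.abs(qq) > 1e-14, qq, 1.0), np.inf)
        lin = -cc / np.where(np.abs(b) > 1e-14, b, 1.0)
    t1 = np.where(np.abs(a) <= 1e-14, lin, t1)
    # pick the root on the vertex branch: smaller |z_local|
    z1 = p[:, 2] + t1 * d[:, 2]
    z2 = p[:, 2] + t2 * d[:, 2]
    use2 = np.abs(z2) < np.abs(z1)
    t = np.where(use2, t2, t1)
    ok &= np.isfinite(t) & (t > -1e-9)
    return t, ok


def _intersect_newton(p, d, surface: ConicSurface, cone, max_iter=25, tol=1e-11):
    """Damped-Newton intersection on the sag function for toric or
    cone-perturbed surfaces.  Local coordinates; returns (t, ok)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (0.0 - p[:, 2]) / d[:, 2]
    t = np.where(np.isfinite(t), t, 0.0)
    ok = np.ones(len(t), dtype=bool)
    for _ in range(max_iter):
        x = p[:, 0] + t * d[:, 0]
        y = p[:, 1] + t * d[:, 1]
        z = p[:, 2] + t * d[:, 2]
        sag, gx, gy = surface_sag_and_gradient(surface, x, y, cone)
        g = z - sag
        gp = d[:, 2] - (gx * d[:, 0] + gy * d[:, 1])
        bad = ~np.isfinite(g) | ~np.isfinite(gp) | (np.abs(gp) < 1e-14)
        ok &= ~bad
        step = np.where(bad, 0.0, g / np.where(bad, 1.0, gp))
        # damping guards against overshoot on steep cone flanks
        step = np.clip(step, -1.0, 1.0)
        t = t - step
        if np.all(np.abs(np.where(ok, g, 0.0)) < tol):
            break
    x = p[:, 0] + t * d[:, 0]
    y = p[:, 1] + t * d[:, 1]
    z = p[:, 2] + t * d[:, 2]
    sag, _, _ = surface_sag_and_gradient(surface, x, y, cone)
    ok &= np.isfinite(sag) & (np.abs(z - sag) < 1e-8) & (t > -1e-9)
    return t, ok


def intersect_conic(p, d, surface: ConicSurface, cone: Optional[ConeParams] = None):
    """Intersection point and outward normal for a ray bundle with one
    surface (local coordinates: surface vertex at origin).

    Returns (point (N,3), normal (N,3), ok (N,))."""
    p = np.atleast_2d(np.asarray(p, float))
    d = np.atleast_2d(np.asarray(d, float))
    simple = (not surface.is_toric) and (cone is None or cone.amplitude_um == 0)
    if simple:
        t, ok = _intersect_conic_closed(p, d, surface.curvature, surface.conic)
    else:
        t, ok = _intersect_newton(p, d, surface, cone)
    t = np.where(ok, t, 0.0)
    pt = p + t[:, None] * d
    _, gx, gy = surface_sag_and_gradient(surface, pt[:, 0], pt[:, 1], cone)
    nvec = np.stack([-gx, -gy, np.ones_like(gx)], axis=1)
    nvec /= np.linalg.norm(nvec, axis=1, keepdims=True)
    r2 = pt[:, 0] ** 2 + pt[:, 1] ** 2
    ok &= r2 <= surface.semi_aperture_mm**2
    ok &= np.isfinite(pt).all(axis=1) & np.isfinite(nvec).all(axis=1)
    return pt, nvec, ok


def refract_ray(d, normal, n_in: float, n_out: float):
    """Vector Snell refraction of a direction bundle.

    Returns (d_out (N,3), ok (N,)); ``ok`` is False on total internal
    reflection."""
    d = np.atleast_2d(np.asarray(d, float))
    n = np.atleast_2d(np.asarray(normal, float))
    ci = -np.sum(d * n, axis=1)
    flip = ci < 0
    n = np.where(flip[:, None], -n, n)
    ci = np.abs(ci)
    eta = n_in / n_out
    s2 = eta * eta * (1.0 - ci * ci)
    ok = s2 <= 1.0
    ct = np.sqrt(np.maximum(1.0 - s2, 0.0))
    d_out = eta * d + (eta * ci - ct)[:, None] * n
    d_out /= np.linalg.norm(d_out, axis=1, keepdims=True)
    return d_out, ok


# --------------------------------------------------------------------------
# Full system trace


def _build_stack(eye: EyeBiometry, lens: Optional[CorrectionLens]):
    """Global surface stack: list of (z_vertex, surface, cone, n_in, n_out)."""
    stack = []
    if lens is not None:
        ant, post = lens.surfaces
        z_post = -post.thickness_mm
        z_ant = z_post - ant.thickness_mm
        stack.append((z_ant, ant, None, 1.0, ant.n_after))
        stack.append((z_post, post, None, ant.n_after, post.n_after))
        n_in = post.n_after
    else:
        n_in = 1.0
    z = 0.0
    for i, s in enumerate(eye.surfaces):
        cone = eye.cone if (i == 0 and eye.cone.amplitude_um > 0) else None
        stack.append((z, s, cone, n_in, s.n_after))
        n_in = s.n_after
        z += s.thickness_mm
    return stack


def _front_magnification(stack, z_launch, z_pupil):
    """Paraxial height magnification from the launch plane to the physical
    pupil plane for parallel input (mean meridian for toric surfaces)."""
    els = []
    z_prev = z_launch
    for (zv, s, cone, n_in, n_out) in stack:
        if zv >= z_pupil - 1e-9:
            break
        els.append(("T", zv - z_prev, n_in))
        c1, c2 = s.curvatures()
        r_eff = 2.0 / (c1 + c2)
        els.append(("R", paraxial.surface_power(n_in, n_out, r_eff)))
        z_prev = zv
        n_last = n_out
    els.append(("T", z_pupil - z_prev, n_last))
    m = paraxial.system_matrix(els)
    return m[0, 0]


def _exit_pupil_z(eye: EyeBiometry) -> float:
    """Paraxial image of the pupil plane through the crystalline lens."""
    lens_f, lens_b = eye.surfaces[2], eye.surfaces[3]
    n_aq = eye.surfaces[1].n_after
    m = paraxial.system_matrix(
        [
            ("R", paraxial.surface_power(n_aq, lens_f.n_after, lens_f.radius_mm)),
            ("T", lens_f.thickness_mm, lens_f.n_after),
            ("R", paraxial.surface_power(lens_f.n_after, lens_b.n_after, lens_b.radius_mm)),
        ]
    )
    d_mm, _ = paraxial.image_of_plane(m, lens_b.n_after)
    z_lens_back = eye.pupil_z_mm + lens_f.thickness_mm
    return z_lens_back + d_mm


def trace_system(
    eye: EyeBiometry,
    lens: Optional[CorrectionLens] = None,
    samples_norm: Optional[np.ndarray] = None,
    wavelength_nm: float = 555.0,
    max_loss_fraction: float = 0.2,
) -> TraceResult:
    """Trace the correction + eye and return exit-pupil OPD samples.

    ``samples_norm`` are normalized physical-pupil coordinates (default:
    the 121-ray hexapolar pattern); the first sample must be the pupil
    centre.  Raises :class:`TraceError` when more than
    ``max_loss_fraction`` of the rays are lost.
    """
    if samples_norm is None:
        samples_norm = pupil_samples()
    samples_norm = np.asarray(samples_norm, float)
    if not np.allclose(samples_norm[0], 0.0):
        raise ValueError("first pupil sample must be the chief ray (0, 0)")
    n_rays = len(samples_norm)
    pupil_r = eye.pupil_diameter_mm / 2.0
    stack = _build_stack(eye, lens)
    z_first = stack[0][0]
    z_launch = z_first - 1.0
    z_pupil = eye.pupil_z_mm
    z_retina = eye.pupil_z_mm + eye.surfaces[2].thickness_mm + eye.retina_distance_mm

    mag = _front_magnification(stack, z_launch, z_pupil)
    if not np.isfinite(mag) or abs(mag) < 1e-6:
        raise TraceError("degenerate entrance-pupil magnification")

    pos = np.zeros((n_rays, 3))
    pos[:, :2] = samples_norm * pupil_r / mag
    pos[:, 2] = z_launch
    d = np.zeros((n_rays, 3))
    d[:, 2] = 1.0
    opl = np.zeros(n_rays)
    ok = np.ones(n_rays, dtype=bool)
    pupil_xy = np.full((n_rays, 2), np.nan)

    for (zv, surf, cone, n_in, n_out) in stack:
        if abs(zv - z_pupil) < 1e-9:
            # record achieved physical-pupil crossing before this surface
            with np.errstate(divide="ignore", invalid="ignore"):
                tq = (z_pupil - pos[:, 2]) / d[:, 2]
            pupil_xy = pos[:, :2] + tq[:, None] * d[:, :2]
        local = pos.copy()
        local[:, 2] -= zv
        pt, nvec, hit = intersect_conic(local, d, surf, cone)
        seg = np.linalg.norm(pt - local, axis=1)
        opl = opl + n_in * seg
        pt[:, 2] += zv
        d_new, not_tir = refract_ray(d, nvec, n_in, n_out)
        ok &= hit & not_tir
        pos = np.where(ok[:, None], pt, pos)
        d = np.where(ok[:, None], d_new, d)

    if not ok[0]:
        raise TraceError("chief ray lost")
    n_lost = int(np.sum(~ok))
    if n_lost > max_loss_fraction * n_rays:
        raise TraceError(f"{n_lost}/{n_rays} rays lost: unphysical configuration")

    n_v = stack[-1][4]
    # chief retinal intersection
    t_ret = (z_retina - pos[0, 2]) / d[0, 2]
    chief_retina = pos[0] + t_ret * d[0]
    z_xp = _exit_pupil_z(eye)
    ref_center = chief_retina
    ref_radius = float(np.linalg.norm(chief_retina - np.array([0.0, 0.0, z_xp])))

    pc = pos - ref_center
    b = np.sum(d * pc, axis=1)
    c0 = np.sum(pc * pc, axis=1) - ref_radius**2
    disc = b * b - c0
    ok &= disc >= 0.0
    t_sph = -b - np.sqrt(np.maximum(disc, 0.0))
    total = opl + n_v * t_sph
    opd_um = (total[0] - total) * 1000.0
    opd_um[0] = 0.0

    return TraceResult(
        pupil_xy_norm=pupil_xy / pupil_r,
        opd_um=np.where(ok, opd_um, np.nan),
        valid=ok,
        n_lost=n_lost,
        chief_retina_xy_mm=(float(chief_retina[0]), float(chief_retina[1])),
        exit_pupil_z_mm=z_xp,
        pupil_radius_mm=pupil_r,
    )
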