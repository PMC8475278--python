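"""Trace-to-wavefront analysis: the glue between ray tracing, Zernike
fitting, and objective refraction.

Two pupil-radius labels are attached to the same fitted wavefront:

* the *physical* label (2.5 mm) used by the image-quality chain, so PSFs are
  computed for a 5-mm aperture;
* the *dioptric* label used by the refraction formulas, chosen so that the
  second-order coefficients read directly in spectacle-plane diopters.

The wavefront is sampled over the exit pupil, whose radius differs from the
physical pupil's by the crystalline-lens imaging magnification; in addition
a spectacle's power reaches the exit pupil through the eye's front optics
with a vergence magnification (vertex effectivity plus pupil imaging).  Both
factors are computed paraxially per eye and folded into one equivalent
radius, so that prescribing the Zernike refraction as a spectacle nulls the
residual second-order terms in a single step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import paraxial
from .correction import CorrectionLens, LENS_GEOMETRY
from .eye import EyeBiometry
from .raytrace import TraceResult, trace_system
from .refraction import (
    SpherocylRx,
    rx_to_power_vector,
    seidel_refraction,
    zernike_refraction,
)
from .zernike import WavefrontCoefficients, fit_zernike

__all__ = ["TraceAnalysis", "analyze_eye", "exit_pupil_magnification", "dioptric_pupil_radius"]


def exit_pupil_magnification(eye: EyeBiometry) -> float:
    """Paraxial magnification of the physical pupil imaged into the vitreous
    through the crystalline lens."""
    lf, lb = eye.surfaces[2], eye.surfaces[3]
    m = paraxial.system_matrix(
        [
            ("R", paraxial.surface_power(eye.surfaces[1].n_after, lf.n_after, lf.radius_mm)),
            ("T", lf.thickness_mm, lf.n_after),
            ("R", paraxial.surface_power(lf.n_after, lb.n_after, lb.radius_mm)),
        ]
    )
    _, mag = paraxial.image_of_plane(m, lb.n_after)
    return abs(mag)


def _exit_pupil_vergence_error(eye: EyeBiometry, spectacle_power_D: float) -> float:
    """Paraxial vergence error at the exit-pupil plane for the eye wearing a
    thin correction of the given power at the spectacle plane."""
    from .raytrace import _exit_pupil_z

    z_s = -LENS_GEOMETRY["spectacle"]["standoff_mm"]
    els = [("R", spectacle_power_D), ("T", -z_s, 1.0)]
    els += eye.paraxial_elements()[:-1]  # up to the last refraction
    z_xp = _exit_pupil_z(eye)
    z_back = eye.pupil_z_mm + eye.surfaces[2].thickness_mm
    n_v = eye.surfaces[3].n_after
    els.append(("T", z_xp - z_back, n_v))
    m = paraxial.system_matrix(els)
    y, w = m[0, 0], m[1, 0]  # parallel input (1, 0)
    v_bundle = -w / y
    z_ret = z_back + eye.retina_distance_mm
    v_ref = n_v / ((z_ret - z_xp) * 1e-3)
    return v_bundle - v_ref


def dioptric_pupil_radius(eye: EyeBiometry, method: str = "traced") -> float:
    """Equivalent pupil radius (mm) that makes second-order Zernike
    refraction read in spectacle-plane diopters.

    ``method="paraxial"`` combines the exit-pupil radius with the paraxial
    spectacle-to-exit-pupil vergence response d(V_xp)/d(P_spectacle).
    ``method="traced"`` (default) measures the defocus response slope
    directly with two traces at +/-1 D, which also captures the thick-lens
    shape factor; the paraxial route serves as its independent cross-check.
    """
    if method == "traced":
        from .correction import make_correction

        dc = []
        for p in (1.0, -1.0):
            lens = make_correction(SpherocylRx(p, 0.0, 0.0), "spectacle")
            tr = trace_system(eye, lens)
            w = fit_zernike(
                tr.pupil_xy_norm[:, 0], tr.pupil_xy_norm[:, 1], tr.opd_um,
                eye.pupil_diameter_mm / 2.0,
            )
            dc.append(w.c(2, 0))
        slope = (dc[0] - dc[1]) / 2.0  # d c20 / d P: positive (plus lens -> myopic shift)
        if not np.isfinite(slope) or slope <= 0:
            raise ValueError("degenerate spectacle response slope")
        # require -4*sqrt(3)*(dc20/dP)/r^2 == -1 (adding +1 D shifts M by -1 D)
        return float(np.sqrt(4.0 * np.sqrt(3.0) * slope))
    if method != "paraxial":
        raise ValueError(f"unknown method {method!r}")
    r_xp = (eye.pupil_diameter_mm / 2.0) * exit_pupil_magnification(eye)
    eps = 0.5
    k = (
        _exit_pupil_vergence_error(eye, eps) - _exit_pupil_vergence_error(eye, -eps)
    ) / (2.0 * eps)
    if not np.isfinite(k) or k <= 0:
        raise ValueError("degenerate spectacle response factor")
    return r_xp * float(np.sqrt(k))


@dataclass
class TraceAnalysis:
    """Fitted wavefront of one trace with both pupil-radius labels."""

    trace: TraceResult
    wavefront: WavefrontCoefficients  # physical 5-mm label, for PSF/VSX
    wavefront_dioptric: WavefrontCoefficients  # spectacle-diopter label

    @property
    def zernike_rx(self) -> SpherocylRx:
        return zernike_refraction(self.wavefront_dioptric)

    @property
    def seidel_rx(self) -> SpherocylRx:
        return seidel_refraction(self.wavefront_dioptric)

    def residual_blur_D(self) -> float:
        """Magnitude of the residual Seidel power vector (diopters)."""
        return rx_to_power_vector(self.seidel_rx).blur_strength()


def analyze_eye(
    eye: EyeBiometry,
    lens: Optional[CorrectionLens] = None,
    samples_norm: Optional[np.ndarray] = None,
    dioptric_radius_mm: Optional[float] = None,
) -> TraceAnalysis:
    """Trace the (corrected) eye and fit its exit-pupil wavefront.

    ``dioptric_radius_mm`` can be passed in to avoid recomputing the
    paraxial conversion when scanning many corrections on one eye.
    """
    tr = trace_system(eye, lens, samples_norm)
    r_d = dioptric_radius_mm or dioptric_pupil_radius(eye)
    x = tr.pupil_xy_norm[:, 0]
    y = tr.pupil_xy_norm[:, 1]
    w_phys = fit_zernike(x, y, tr.opd_um, eye.pupil_diameter_mm / 2.0)
    w_dpt = WavefrontCoefficients(w_phys.coeffs, r_d, w_phys.residual_rms_um)
    return TraceAnalysis(trace=tr, wavefront=w_phys, wavefront_dioptric=w_dpt)
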