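"""Visual image quality: point spread function, neural weighting, VSX.

The PSF is the standard Fourier-optics far field of the generalized pupil
function exp(i 2*pi W / lambda) over the circular 5-mm aperture, zero-padded
to avoid wrap-around.  VSX is the inner product of the PSF with a neural
weighting function centred on the PSF peak, normalized by the same inner
product for the diffraction-limited PSF.

The neural weighting is the spatial kernel of a photopic neural contrast
sensitivity function parametrized as N(f) = exp(-f / f0) with f0 = 7
cycles/degree; its two-dimensional inverse Fourier transform has the closed
form  NW(r) ~ (1 + (2*pi*f0*r)^2)^(-3/2), which is positive, peaked at the
origin and radially decreasing.  The constants are frozen here and
unit-tested; absolute VSX values depend on this parametrization and the eye
templates are calibrated with it in place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import fft as sp_fft
from scipy.signal import fftconvolve

from .zernike import WavefrontCoefficients, zernike_basis

__all__ = [
    "PsfGrid",
    "NeuralWeight",
    "VsxEngine",
    "neural_weight_profile",
    "compute_psf",
    "neural_weighting",
    "vsx",
    "render_chart",
    "tumbling_e_chart",
    "NEURAL_CSF_F0_CPD",
]

NEURAL_CSF_F0_CPD = 7.0  # exponential photopic neural CSF constant


@dataclass
class PsfGrid:
    """Sampled PSF over visual angle, normalized to unit sum."""

    intensity: np.ndarray
    pixel_scale_arcmin: float
    wavelength_nm: float = 555.0

    def __post_init__(self) -> None:
        total = float(np.sum(self.intensity))
        if not np.isfinite(total) or total <= 0:
            raise ValueError("PSF intensities must sum to a positive finite value")

    @property
    def peak_index(self) -> tuple:
        return tuple(np.unravel_index(int(np.argmax(self.intensity)), self.intensity.shape))


@dataclass
class NeuralWeight:
    """Neural weighting sampled on the same angular grid as the PSF."""

    weights: np.ndarray
    pixel_scale_arcmin: float


def neural_weight_profile(r_arcmin, f0_cpd: float = NEURAL_CSF_F0_CPD):
    """Closed-form spatial kernel of the exponential neural CSF, peak = 1."""
    r = np.asarray(r_arcmin, float)
    x = 2.0 * math.pi * f0_cpd * r / 60.0
    return (1.0 + x * x) ** -1.5


class VsxEngine:
    """Precomputed pipeline from Zernike coefficients to PSF and VSX.

    The pupil plane is sampled on an N x N grid across the 5-mm aperture and
    zero-padded by ``pad_factor`` before the FFT, giving an angular pixel of
    lambda / (pad * D).  The neural weighting and the diffraction-limited
    reference are evaluated once at construction.
    """

    def __init__(
        self,
        pupil_diameter_mm: float = 5.0,
        wavelength_um: float = 0.555,
        pupil_grid: int = 256,
        pad_factor: int = 2,
        csf_f0_cpd: float = NEURAL_CSF_F0_CPD,
        max_order: int = 8,
    ):
        if pupil_grid < 64:
            raise ValueError("pupil grid too coarse")
        if pad_factor < 2:
            raise ValueError("zero-padding factor must be >= 2")
        self.pupil_diameter_mm = pupil_diameter_mm
        self.wavelength_um = wavelength_um
        self.pupil_grid = pupil_grid
        self.pad_factor = pad_factor
        self.csf_f0_cpd = csf_f0_cpd
        self.n_fft = pupil_grid * pad_factor
        # angular pixel in radians, then arcmin
        lam_mm = wavelength_um * 1e-3
        self.pixel_scale_rad = lam_mm / (pad_factor * pupil_diameter_mm)
        self.pixel_scale_arcmin = math.degrees(self.pixel_scale_rad) * 60.0

        c = (np.arange(pupil_grid) + 0.5) / pupil_grid * 2.0 - 1.0
        gx, gy = np.meshgrid(c, c)
        self.mask = gx * gx + gy * gy <= 1.0
        self._mask_idx = np.where(self.mask)
        self.n_mask = int(np.sum(self.mask))
        self.basis = zernike_basis(gx[self.mask], gy[self.mask], max_order).T.astype(
            np.float64
        )  # (nterms, n_mask)

        n = self.n_fft
        ax = (np.arange(n) - n // 2) * self.pixel_scale_arcmin
        wx, wy = np.meshgrid(ax, ax)
        r = np.hypot(wx, wy)
        self.neural = neural_weight_profile(r, csf_f0_cpd).astype(np.float32)

        self._dl_psf_raw = self._raw_psf(np.zeros(self.basis.shape[0]))
        self._dl_inner = self._peak_inner(self._dl_psf_raw)
        if self._dl_inner <= 0:
            raise ValueError("degenerate diffraction-limited reference")

    # ------------------------------------------------------------------
    def _phase(self, coeffs: np.ndarray) -> np.ndarray:
        c = np.zeros(self.basis.shape[0])
        m = min(len(coeffs), len(c))
        c[:m] = coeffs[:m]
        c[:3] = 0.0  # piston and tilt carry no image-quality information
        w_um = c @ self.basis
        return (2.0 * math.pi / self.wavelength_um) * w_um

    def _raw_psf(self, coeffs: np.ndarray) -> np.ndarray:
        """Unnormalized PSF in wrapped (unshifted) FFT layout."""
        phase = self._phase(np.asarray(coeffs, float)).astype(np.float32)
        field = np.zeros((self.pupil_grid, self.pupil_grid), dtype=np.complex64)
        field[self._mask_idx] = np.cos(phase) + 1j * np.sin(phase)
        f = sp_fft.fft2(field, s=(self.n_fft, self.n_fft))
        return (f.real**2 + f.imag**2).astype(np.float32)

    def _peak_inner(self, raw_psf: np.ndarray) -> float:
        """Neurally weighted sum with the weighting centred on the PSF peak
        (layout-agnostic: np.roll wraps, matching the FFT periodicity)."""
        iy, ix = np.unravel_index(int(np.argmax(raw_psf)), raw_psf.shape)
        n = self.n_fft
        rolled = np.roll(np.roll(raw_psf, n // 2 - iy, axis=0), n // 2 - ix, axis=1)
        return float(np.sum(rolled * self.neural, dtype=np.float64))

    def check_sampling(self, coeffs: np.ndarray) -> bool:
        """True when the pupil-plane phase is Nyquist-adequate (adjacent
        sample phase steps below pi)."""
        phase = self._phase(np.asarray(coeffs, float))
        full = np.full((self.pupil_grid, self.pupil_grid), np.nan)
        full[self._mask_idx] = phase
        for d in (np.diff(full, axis=0), np.diff(full, axis=1)):
            step = np.abs(d[np.isfinite(d)])
            if step.size and step.max() >= math.pi:
                return False
        return True

    # ------------------------------------------------------------------
    def psf(self, w: WavefrontCoefficients, check: bool = False) -> PsfGrid:
        if check and not self.check_sampling(w.coeffs):
            raise ValueError("pupil grid too coarse for this wavefront (aliasing)")
        raw = sp_fft.fftshift(self._raw_psf(w.coeffs))
        total = float(np.sum(raw, dtype=np.float64))
        return PsfGrid(raw / total, self.pixel_scale_arcmin, self.wavelength_um * 1e3)

    def neural_weight(self) -> NeuralWeight:
        return NeuralWeight(self.neural.copy(), self.pixel_scale_arcmin)

    def vsx(self, w: WavefrontCoefficients) -> float:
        """Visual Strehl: neurally weighted PSF concentration, peak-centred,
        normalized to the diffraction-limited case."""
        return self._peak_inner(self._raw_psf(w.coeffs)) / self._dl_inner

    def vsx_from_psf(self, psf: PsfGrid) -> float:
        if abs(psf.pixel_scale_arcmin - self.pixel_scale_arcmin) > 1e-9:
            raise ValueError("PSF grid does not match the engine grid")
        dl_unit = self._dl_inner / float(np.sum(self._dl_psf_raw, dtype=np.float64))
        p_unit = self._peak_inner(psf.intensity) / float(
            np.sum(psf.intensity, dtype=np.float64)
        )
        return p_unit / dl_unit


# --------------------------------------------------------------------------
# Functional API


_DEFAULT_ENGINE: Optional[VsxEngine] = None


def default_engine() -> VsxEngine:
    global _DEFAULT_ENGINE
    if _DEFAULT_ENGINE is None:
        _DEFAULT_ENGINE = VsxEngine()
    return _DEFAULT_ENGINE


def compute_psf(
    w: WavefrontCoefficients, engine: Optional[VsxEngine] = None, check: bool = True
) -> PsfGrid:
    return (engine or default_engine()).psf(w, check=check)


def neural_weighting(engine: Optional[VsxEngine] = None) -> NeuralWeight:
    return (engine or default_engine()).neural_weight()


def vsx(psf: PsfGrid, nw: NeuralWeight, reference_psf: PsfGrid) -> float:
    """Inner product of the PSF with the neural weighting, each centred on
    its own peak, normalized to the reference (diffraction-limited) PSF."""
    if abs(psf.pixel_scale_arcmin - nw.pixel_scale_arcmin) > 1e-9:
        raise ValueError("PSF and neural weighting grids differ")

    def inner(p: PsfGrid) -> float:
        iy, ix = p.peak_index
        n0, n1 = p.intensity.shape
        rolled = np.roll(np.roll(p.intensity, n0 // 2 - iy, axis=0), n1 // 2 - ix, axis=1)
        return float(np.sum(rolled * nw.weights, dtype=np.float64))

    denom = inner(reference_psf)
    if denom <= 0:
        raise ValueError("zero reference inner product: grid misconfiguration")
    return inner(psf) / denom


# --------------------------------------------------------------------------
# Acuity-chart simulation


def _letter_e(cell: int) -> np.ndarray:
    """Tumbling-E glyph on a 5x5 stroke grid, opening to the right."""
    g = np.ones((5 * cell, 5 * cell))
    g[:, :cell] = 0.0  # spine
    for row in (0, 2, 4):
        g[row * cell : (row + 1) * cell, :] = 0.0
    return g


def tumbling_e_chart(
    logmar_lines=(0.5, 0.4, 0.3, 0.2, 0.1, 0.0),
    pixel_scale_arcmin: float = 0.25,
    letters_per_line: int = 4,
    rng=None,
) -> np.ndarray:
    """Rasterize a logMAR tumbling-E chart (white background = 1.0).

    Letter height is 5x the minimum angle of resolution, 10^logMAR arcmin.
    """
    import numpy.random as npr

    rng = rng or npr.default_rng(0)
    rows = []
    width = 0
    for lm in logmar_lines:
        mar = 10.0**lm
        cell = max(1, int(round(mar / pixel_scale_arcmin)))
        glyphs = []
        for _ in range(letters_per_line):
            e = _letter_e(cell)
            e = np.rot90(e, k=int(rng.integers(0, 4)))
            pad = np.ones((5 * cell, 2 * cell))
            glyphs.extend([e, pad])
        row = np.concatenate(glyphs[:-1], axis=1)
        gap = np.ones((3 * cell, row.shape[1]))
        block = np.concatenate([row, gap], axis=0)
        rows.append(block)
        width = max(width, block.shape[1])
    padded = []
    for b in rows:
        extra = width - b.shape[1]
        padded.append(np.pad(b, ((0, 0), (0, extra)), constant_values=1.0))
    chart = np.concatenate(padded, axis=0)
    return np.pad(chart, 8, constant_values=1.0)


def render_chart(psf: PsfGrid, chart: np.ndarray, chart_pixel_scale_arcmin: float) -> np.ndarray:
    """Convolve an acuity chart with the PSF (simulated retinal image).

    The chart must be sampled at the PSF's angular pixel scale; the output
    preserves the input luminance range (unit-sum kernel).
    """
    if abs(chart_pixel_scale_arcmin - psf.pixel_scale_arcmin) > 1e-9:
        raise ValueError("chart pixel scale must match the PSF grid")
    kernel = psf.intensity / float(np.sum(psf.intensity))
    # trim negligible kernel margins to keep the convolution cheap
    iy, ix = np.unravel_index(int(np.argmax(kernel)), kernel.shape)
    prof = np.maximum(kernel.max(axis=0), kernel.max(axis=1))
    keep = np.where(prof > kernel.max() * 1e-6)[0]
    if keep.size:
        lo, hi = keep.min(), keep.max() + 1
        kernel = kernel[lo:hi, lo:hi]
    return fftconvolve(chart, kernel, mode="same")
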