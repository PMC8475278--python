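"""Normalized (OSA/ANSI) Zernike polynomials, wavefront fitting, rescaling.

Coefficients are stored in OSA single-index order j = (n(n+2)+m)/2 for all
terms up to a maximum radial order (default 8, i.e. 45 terms).  Units are
micrometres over a stated pupil radius; piston and tilt are carried in the
fit but excluded from all metrics downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor as scipy_cho_factor, cho_solve as scipy_cho_solve

__all__ = [
    "WavefrontCoefficients",
    "osa_index",
    "osa_nm",
    "zernike_basis",
    "fit_zernike",
    "rescale_coefficients",
    "N_TERMS_ORDER8",
]

MAX_ORDER_DEFAULT = 8
N_TERMS_ORDER8 = (MAX_ORDER_DEFAULT + 1) * (MAX_ORDER_DEFAULT + 2) // 2  # 45


def osa_index(n: int, m: int) -> int:
    return (n * (n + 2) + m) // 2


def osa_nm(j: int) -> tuple[int, int]:
    n = int((math.sqrt(8 * j + 1) - 1) // 2)
    m = 2 * j - n * (n + 2)
    return n, m


def _radial_coeffs(n: int, m: int) -> list[tuple[float, int]]:
    """(coefficient, power) pairs of the radial polynomial R_n^|m|."""
    m = abs(m)
    out = []
    for s in range((n - m) // 2 + 1):
        c = (
            (-1) ** s
            * math.factorial(n - s)
            / (
                math.factorial(s)
                * math.factorial((n + m) // 2 - s)
                * math.factorial((n - m) // 2 - s)
            )
        )
        out.append((float(c), n - 2 * s))
    return out


def _norm(n: int, m: int) -> float:
    return math.sqrt(2.0 * (n + 1) / (1.0 + (1.0 if m == 0 else 0.0)))


def _zernike_basis_direct(x, y, max_order: int) -> np.ndarray:
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    rho = np.hypot(x, y)
    theta = np.arctan2(y, x)
    nterms = (max_order + 1) * (max_order + 2) // 2
    pows = {0: np.ones_like(rho)}
    for p in range(1, max_order + 1):
        pows[p] = pows[p - 1] * rho
    cols = np.empty((nterms, rho.size))
    for j in range(nterms):
        n, m = osa_nm(j)
        r = np.zeros_like(rho)
        for c, p in _radial_coeffs(n, m):
            r += c * pows[p]
        if m > 0:
            ang = np.cos(m * theta)
        elif m < 0:
            ang = np.sin(-m * theta)
        else:
            ang = 1.0
        cols[j] = _norm(n, m) * r * ang
    return cols.T


def _monomial_exponents(max_order: int):
    return [(i - j, j) for i in range(max_order + 1) for j in range(i + 1)]


_MONO_CACHE: dict = {}


def _monomial_transform(max_order: int) -> np.ndarray:
    """Exact change of basis from Cartesian monomials x^a y^b (total degree
    <= max_order) to the Zernike basis; cached (Zernikes are polynomials, so
    the transform is exact)."""
    t = _MONO_CACHE.get(max_order)
    if t is None:
        rng = np.random.default_rng(12345)
        npts = 4 * (max_order + 1) * (max_order + 2)
        r = np.sqrt(rng.uniform(0, 1, npts))
        a = rng.uniform(0, 2 * math.pi, npts)
        xs, ys = r * np.cos(a), r * np.sin(a)
        mono = _monomials(xs, ys, max_order)
        direct = _zernike_basis_direct(xs, ys, max_order)
        t, *_ = np.linalg.lstsq(mono, direct, rcond=None)
        _MONO_CACHE[max_order] = t
    return t


def _monomials(x, y, max_order: int) -> np.ndarray:
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    xp = [np.ones_like(x)]
    yp = [np.ones_like(y)]
    for _ in range(max_order):
        xp.append(xp[-1] * x)
        yp.append(yp[-1] * y)
    cols = [xp[a] * yp[b] for a, b in _monomial_exponents(max_order)]
    return np.stack(cols, axis=1)


def zernike_basis(x, y, max_order: int = MAX_ORDER_DEFAULT) -> np.ndarray:
    """Matrix of Zernike values, shape (npoints, nterms), on normalized
    pupil coordinates (x, y)."""
    return _monomials(x, y, max_order) @ _monomial_transform(max_order)


@dataclass
class WavefrontCoefficients:
    """Eighth-order normalized Zernike expansion of a wavefront (micrometres).

    ``coeffs`` holds all OSA terms j = 0..44 (piston/tilt retained for
    completeness but ignored by the image-quality and refraction code).
    """

    coeffs: np.ndarray
    pupil_radius_mm: float
    residual_rms_um: float = 0.0

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, float)
        if self.pupil_radius_mm <= 0:
            raise ValueError("pupil_radius_mm must be > 0")

    def c(self, n: int, m: int) -> float:
        return float(self.coeffs[osa_index(n, m)])

    @property
    def metric_coeffs(self) -> np.ndarray:
        """Coefficients with piston and tilt zeroed (orders 2..8)."""
        out = self.coeffs.copy()
        out[:3] = 0.0
        return out

    def hoa_rms_um(self) -> float:
        """Root-mean-square of third- and higher-order terms."""
        return float(np.sqrt(np.sum(self.coeffs[6:] ** 2)))

    def to_table(self) -> "list[tuple[int, int, int, float]]":
        return [(j, *osa_nm(j), float(cv)) for j, cv in enumerate(self.coeffs)]

    def to_csv(self, path) -> None:
        """Single-index CSV with the pupil radius recorded in a header row."""
        with open(path, "w") as fh:
            fh.write(f"# pupil_radius_mm,{self.pupil_radius_mm}\n")
            fh.write("j,n,m,coefficient_um\n")
            for j, n, m, c in self.to_table():
                fh.write(f"{j},{n},{m},{c!r}\n")

    @classmethod
    def from_csv(cls, path) -> "WavefrontCoefficients":
        with open(path) as fh:
            header = fh.readline().strip()
            radius = float(header.split(",")[1])
            fh.readline()
            coeffs = [float(line.split(",")[3]) for line in fh if line.strip()]
        return cls(np.asarray(coeffs), radius)


def fit_zernike(
    x_norm,
    y_norm,
    opd_um,
    pupil_radius_mm: float,
    max_order: int = MAX_ORDER_DEFAULT,
    min_samples: int = 90,
) -> WavefrontCoefficients:
    """Least-squares Zernike fit of OPD samples on normalized coordinates.

    Raises ``ValueError`` when fewer than ``min_samples`` valid samples are
    supplied or the design matrix is rank deficient (clustered samples).
    """
    x = np.asarray(x_norm, float).ravel()
    y = np.asarray(y_norm, float).ravel()
    w = np.asarray(opd_um, float).ravel()
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(w)
    x, y, w = x[ok], y[ok], w[ok]
    if x.size < min_samples:
        raise ValueError(f"only {x.size} valid samples (need >= {min_samples})")
    basis = zernike_basis(x, y, max_order)
    # normal equations with a Cholesky solve; the hexapolar design is well
    # conditioned, and a failed factorization flags clustered samples
    gram = basis.T @ basis
    try:
        cf = scipy_cho_factor(gram)
        coeffs = scipy_cho_solve(cf, basis.T @ w)
    except Exception as exc:  # LinAlgError: not positive definite
        raise ValueError("rank-deficient Zernike design matrix (clustered samples)") from exc
    if not np.all(np.isfinite(coeffs)):
        raise ValueError("non-finite Zernike fit")
    resid = w - basis @ coeffs
    rms = float(np.sqrt(np.mean(resid**2)))
    return WavefrontCoefficients(coeffs, pupil_radius_mm, rms)


_RESCALE_CACHE: dict = {}


def rescale_coefficients(
    w: WavefrontCoefficients, new_radius_mm: float
) -> WavefrontCoefficients:
    """Express the same wavefront over a smaller (or equal) pupil radius.

    Zernike expansions are closed under radial scaling, so the transform is
    an exact linear map; it is obtained by projecting the basis evaluated on
    scaled coordinates back onto the basis (cached per scale factor).
    """
    s = new_radius_mm / w.pupil_radius_mm
    max_order = osa_nm(len(w.coeffs) - 1)[0]
    key = (round(s, 12), max_order)
    t = _RESCALE_CACHE.get(key)
    if t is None:
        # Quadrature grid dense enough for exact polynomial projection.
        n = 48
        g = (np.arange(n) + 0.5) / n * 2.0 - 1.0
        gx, gy = np.meshgrid(g, g)
        mask = gx**2 + gy**2 <= 1.0
        gx, gy = gx[mask], gy[mask]
        b_full = zernike_basis(gx, gy, max_order)
        b_scaled = zernike_basis(gx * s, gy * s, max_order)
        t, *_ = np.linalg.lstsq(b_full, b_scaled, rcond=None)
        _RESCALE_CACHE[key] = t
    new = t @ w.coeffs
    return WavefrontCoefficients(new, new_radius_mm, w.residual_rms_um)
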