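"""Synthetic-eye generator for normal and keratoconic cohorts.

The generator is a documented stand-in for a full multivariate statistical
eye model: instead of sampling correlated raw biometry, it samples the
clinically meaningful *targets* of each eye (maximal keratometry, objective
sphere and cylinder) from the cohort distributions and then solves the free
biometric parameters - anterior corneal radius, corneal toricity, cone
amplitude, and vitreous depth - so that the *traced* eye reproduces those
targets exactly.  This guarantees the cohort statistics by construction
while every eye remains a fully consistent optical model.

Cohort distributions (mean +/- SD):

=============  ============  ==============
quantity        normal        keratoconus
=============  ============  ==============
Kmax (D)        43.00 1.00    53.69 4.85
sphere (D)      -0.74 3.10    -2.84 5.72
cylinder (D)    -0.78 0.40    -4.27 2.45
=============  ============  ==============

Normal eyes are additionally gated to |sphere| <= 10 D (the typical-eye
inclusion rule); cones are decentred inferiorly by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .eye import (
    EyeBiometry,
    KERATOMETRIC_INDEX,
    compute_keratometry,
    template_normal_eye,
)
from .geometry import ConeParams
from .pipeline import analyze_eye, dioptric_pupil_radius
from .refraction import rx_to_power_vector

__all__ = [
    "CohortParams",
    "NORMAL_DEFAULTS",
    "KERATOCONUS_DEFAULTS",
    "GeneratorError",
    "generate_eye",
    "generate_cohort",
    "default_params",
]

_KD = (KERATOMETRIC_INDEX - 1.0) * 1000.0  # 337.5: K = _KD * curvature(1/mm)


class GeneratorError(RuntimeError):
    """Inconsistent generator configuration (rejection cap exceeded)."""


@dataclass
class CohortParams:
    """Sampling distributions and solver settings for one cohort."""

    cohort: str
    kmax_mean: float
    kmax_sd: float
    kmax_bounds: tuple
    sphere_mean: float
    sphere_sd: float
    sphere_bounds: tuple
    cyl_mean: float
    cyl_sd: float
    cyl_bounds: tuple
    conic_mean: float = -0.45
    conic_sd: float = 0.08
    conic_bounds: tuple = (-0.75, -0.15)
    # keratoconus-only knobs
    has_cone: bool = False
    base_k_mean: float = 43.0
    base_k_sd: float = 1.0
    base_k_sphere_slope: float = -0.45  # steeper base cornea in myopic KC eyes
    sigma_mean: float = 1.4
    sigma_sd: float = 0.25
    sigma_bounds: tuple = (0.9, 2.0)
    sigma_kmax_slope: float = 0.0  # mm of cone width per D of Kmax excess
    decenter_r_mean: float = 1.5
    decenter_r_sd: float = 0.4
    decenter_r_bounds: tuple = (0.6, 2.4)
    decenter_angle_mean_deg: float = -90.0  # inferior
    decenter_angle_sd_deg: float = 25.0
    axial_length_bracket_mm: tuple = (19.0, 29.0)
    max_attempts: int = 40

    def as_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


NORMAL_DEFAULTS = CohortParams(
    cohort="normal",
    kmax_mean=43.00,
    kmax_sd=1.00,
    kmax_bounds=(40.0, 46.5),
    sphere_mean=-0.74,
    sphere_sd=3.10,
    sphere_bounds=(-10.0, 10.0),
    cyl_mean=-0.78,
    cyl_sd=0.40,
    # wide enough that the +/-10 D axial-myopia tail is not silently
    # truncated by redraws (which would bias the cohort sphere mean)
    cyl_bounds=(-2.2, -0.10),
    axial_length_bracket_mm=(20.0, 29.2),
)

KERATOCONUS_DEFAULTS = CohortParams(
    cohort="keratoconus",
    kmax_mean=53.69,
    kmax_sd=4.85,
    kmax_bounds=(46.0, 68.0),
    sphere_mean=-2.84,
    sphere_sd=5.72,
    sphere_bounds=(-16.5, 5.0),
    cyl_mean=-4.27,
    cyl_sd=2.45,
    cyl_bounds=(-10.0, -1.0),
    has_cone=True,
    sigma_mean=1.8,
    sigma_sd=0.2,
    sigma_bounds=(1.0, 3.2),
    sigma_kmax_slope=0.12,
    decenter_r_mean=1.6,
    decenter_r_sd=0.3,
    decenter_r_bounds=(0.8, 2.4),
    axial_length_bracket_mm=(19.0, 29.5),
)


def default_params(cohort: str) -> CohortParams:
    if cohort == "normal":
        return replace(NORMAL_DEFAULTS)
    if cohort == "keratoconus":
        return replace(KERATOCONUS_DEFAULTS)
    raise ValueError(f"unknown cohort {cohort!r}")


_LOC_CACHE: dict = {}


def _centered_loc(mean, sd, bounds):
    """Location parameter whose truncated-normal mean equals ``mean``;
    compensates the bias of asymmetric truncation."""
    key = (mean, sd, bounds)
    loc = _LOC_CACHE.get(key)
    if loc is None:
        from scipy.stats import truncnorm

        lo, hi = bounds

        def tmean(l):
            return truncnorm.mean((lo - l) / sd, (hi - l) / sd, loc=l, scale=sd)

        a, b = mean - 3 * sd, mean + 3 * sd
        if not (tmean(a) < mean < tmean(b)):
            raise GeneratorError(f"cannot centre truncated normal {key}")
        for _ in range(60):
            mid = 0.5 * (a + b)
            if tmean(mid) < mean:
                a = mid
            else:
                b = mid
        loc = 0.5 * (a + b)
        _LOC_CACHE[key] = loc
    return loc


def _truncated_normal(rng, mean, sd, bounds, max_tries=200, stratum=None):
    """Draw from the mean-centred truncated normal.

    ``stratum=(i, n)`` draws by inverse CDF from the i-th of n equal
    probability strata (stratified cohort sampling stabilizes cohort means
    at the configured values without narrowing the per-eye dispersion)."""
    if sd == 0:
        rng.standard_normal()  # keep the draw sequence aligned
        lo, hi = bounds
        if not (lo <= mean <= hi):
            raise GeneratorError(f"degenerate distribution mean {mean} outside {bounds}")
        return mean
    lo, hi = bounds
    loc = _centered_loc(mean, sd, bounds)
    if stratum is not None:
        from scipy.stats import truncnorm

        i, n = stratum
        u = (i + rng.uniform()) / n
        return float(
            truncnorm.ppf(u, (lo - loc) / sd, (hi - loc) / sd, loc=loc, scale=sd)
        )
    for _ in range(max_tries):
        v = loc + sd * rng.standard_normal()
        if lo <= v <= hi:
            return v
    raise GeneratorError(f"rejection sampling failed for N({mean}, {sd}) in {bounds}")


# --------------------------------------------------------------------------
# Traced-measurement helpers


def _measure(eye: EyeBiometry):
    """Traced Seidel refraction as (sphere, J0, J45) in spectacle diopters.

    The first component is the clinical minus-cylinder *sphere* (the
    quantity the cohort sphere targets refer to), not the spherical
    equivalent M = sphere + cylinder/2."""
    r_d = dioptric_pupil_radius(eye)
    an = analyze_eye(eye, dioptric_radius_mm=r_d)
    pv = rx_to_power_vector(an.seidel_rx)
    return np.array([an.seidel_rx.sphere_D, pv.J0, pv.J45])


def _set_anterior_toric(eye: EyeBiometry, c_flat, c_steep, flat_axis_deg) -> None:
    s = eye.surfaces[0]
    if abs(c_steep - c_flat) < 1e-9:
        s.radius_mm = 1.0 / c_flat
        s.toric_radius_mm = None
        s.toric_axis_deg = None
    else:
        s.radius_mm = 1.0 / c_flat
        s.toric_radius_mm = 1.0 / c_steep
        s.toric_axis_deg = flat_axis_deg % 180.0


def _solve_vitreous(eye: EyeBiometry, target_sphere: float, tol=0.02, max_iter=8) -> None:
    """Adjust the vitreous depth until the traced Seidel sphere matches."""
    slope = -2.6  # D per mm of axial elongation, refined by secant steps
    d = eye.retina_distance_mm
    m = _measure(eye)[0]
    for _ in range(max_iter):
        if abs(m - target_sphere) < tol:
            return
        d_new = d + (target_sphere - m) / slope
        d_new = min(max(d_new, 10.0), 24.0)
        eye.retina_distance_mm = d_new
        m_new = _measure(eye)[0]
        if abs(d_new - d) > 1e-6:
            slope = (m_new - m) / (d_new - d)
        d, m = d_new, m_new
    if abs(m - target_sphere) > 5 * tol:
        raise GeneratorError("vitreous-depth solve did not converge")


def _solve_cone_amplitude(eye: EyeBiometry, kmax_target: float, tol=0.02) -> None:
    """Bisection solve of the cone amplitude for the target Kmax (Kmax is
    monotone increasing in amplitude)."""
    base = compute_keratometry(replace_cone(eye, 0.0))["Kmax"]
    if kmax_target <= base + 0.3:
        raise GeneratorError("Kmax target not above the base cornea")

    def kmax_at(a_um):
        eye.cone.amplitude_um = a_um
        return compute_keratometry(eye)["Kmax"]

    lo, hi = 0.0, (kmax_target - base) * eye.cone.sigma_mm**2 / _KD * 1e3
    for _ in range(30):
        if kmax_at(hi) >= kmax_target:
            break
        lo, hi = hi, hi * 1.6
    else:
        raise GeneratorError("cone-amplitude solve did not bracket the target")
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        k = kmax_at(mid)
        if abs(k - kmax_target) < tol:
            return
        if k < kmax_target:
            lo = mid
        else:
            hi = mid
    raise GeneratorError("cone-amplitude solve did not converge")


def replace_cone(eye: EyeBiometry, amplitude_um: float) -> EyeBiometry:
    e = EyeBiometry(
        surfaces=eye.surfaces,
        retina_distance_mm=eye.retina_distance_mm,
        cone=ConeParams(
            eye.cone.center_x_mm, eye.cone.center_y_mm, amplitude_um, eye.cone.sigma_mm
        ),
        pupil_diameter_mm=eye.pupil_diameter_mm,
        label=eye.label,
        axial_length_bracket_mm=eye.axial_length_bracket_mm,
    )
    return e


def _apply_toric_vector(eye: EyeBiometry, v: np.ndarray, base_c: float) -> None:
    """Set the anterior toricity from a J-space vector: the flat meridian
    lies at half the double angle of ``v`` and the curvature span matches a
    cylinder of 2*|v| diopters (mean apical power preserved)."""
    dc_per_d = 1.0 / ((1.376 - 1.0) * 1e3)  # curvature difference worth ~1 D
    vmag = float(np.linalg.norm(v))
    if vmag < 1e-8:
        _set_anterior_toric(eye, base_c, base_c, 0.0)
        return
    phi = 0.5 * math.degrees(math.atan2(v[1], v[0]))
    dcv = 2.0 * vmag * dc_per_d
    _set_anterior_toric(eye, base_c - dcv / 2, base_c + dcv / 2, phi)


def _solve_toricity(eye: EyeBiometry, target_j: np.ndarray, base_c: float, tol=0.06) -> None:
    """Adjust anterior corneal toricity so the traced astigmatic power
    vector (J0, J45) reaches the target.

    Stateless: rebuilds the toricity from the cone-only baseline, probes the
    linear response once, then iterates a damped fixed point."""
    _set_anterior_toric(eye, base_c, base_c, 0.0)
    j0 = _measure(eye)[1:]
    if np.linalg.norm(target_j - j0) < tol:
        return
    probe = np.array([0.5, 0.0])  # 1 D of cylinder at axis 0, in J units
    _apply_toric_vector(eye, probe, base_c)
    resp = _measure(eye)[1:] - j0
    k = float(np.linalg.norm(resp)) / float(np.linalg.norm(probe))
    if not np.isfinite(k) or k < 1e-2:
        raise GeneratorError("degenerate toric response")
    v = (target_j - j0) / k
    best_v, best_err = None, np.inf
    for _ in range(10):
        _apply_toric_vector(eye, v, base_c)
        j = _measure(eye)[1:]
        err = float(np.linalg.norm(j - target_j))
        if err < best_err:
            best_v, best_err = v.copy(), err
        if err < tol:
            return
        v = v + 0.8 * (target_j - j) / k
    _apply_toric_vector(eye, best_v, base_c)
    if best_err > 0.3:
        raise GeneratorError("toricity solve did not converge")


# --------------------------------------------------------------------------


def _generate_normal(rng, p: CohortParams, strata=None) -> EyeBiometry:
    strata = strata or {}
    kmax_t = _truncated_normal(rng, p.kmax_mean, p.kmax_sd, p.kmax_bounds, stratum=strata.get("kmax"))
    sph_t = _truncated_normal(rng, p.sphere_mean, p.sphere_sd, p.sphere_bounds, stratum=strata.get("sphere"))
    cyl_t = _truncated_normal(rng, p.cyl_mean, p.cyl_sd, p.cyl_bounds, stratum=strata.get("cyl"))
    conic = _truncated_normal(
        rng, p.conic_mean, p.conic_sd, p.conic_bounds, stratum=strata.get("conic")
    )
    axis_t = float(rng.uniform(0.0, 180.0))

    c_steep = kmax_t / _KD
    eye = template_normal_eye(anterior_radius_mm=1.0 / c_steep, anterior_conic=conic)
    eye.label = "normal"
    eye.axial_length_bracket_mm = p.axial_length_bracket_mm

    # flat meridian along the minus-cylinder axis; steep stays at Kmax
    dc = abs(cyl_t) / ((1.376 - 1.0) * 1e3)  # first guess, refined below
    for _ in range(6):
        _set_anterior_toric(eye, c_steep - dc, c_steep, (axis_t) % 180.0)
        j = _measure(eye)[1:]
        cyl_meas = -2.0 * np.linalg.norm(j)
        if abs(cyl_meas - cyl_t) < 0.04:
            break
        dc *= abs(cyl_t) / max(abs(cyl_meas), 1e-6)
    _solve_vitreous(eye, sph_t)
    return eye


def _generate_keratoconus(rng, p: CohortParams, strata=None) -> EyeBiometry:
    strata = strata or {}
    kmax_t = _truncated_normal(rng, p.kmax_mean, p.kmax_sd, p.kmax_bounds, stratum=strata.get("kmax"))
    sph_t = _truncated_normal(rng, p.sphere_mean, p.sphere_sd, p.sphere_bounds, stratum=strata.get("sphere"))
    cyl_t = _truncated_normal(rng, p.cyl_mean, p.cyl_sd, p.cyl_bounds, stratum=strata.get("cyl"))
    conic = _truncated_normal(
        rng, p.conic_mean, p.conic_sd, p.conic_bounds, stratum=strata.get("conic")
    )
    axis_t = float(rng.uniform(0.0, 180.0))
    # advanced cones are broader: optionally couple the width to severity
    sigma_loc = p.sigma_mean + p.sigma_kmax_slope * (kmax_t - p.kmax_mean)
    lo_s, hi_s = p.sigma_bounds
    # keep the target mean strictly inside the truncation bracket
    sigma_loc = min(max(sigma_loc, lo_s + 0.7 * p.sigma_sd), hi_s - 0.7 * p.sigma_sd)
    sigma = _truncated_normal(
        rng, sigma_loc, p.sigma_sd, p.sigma_bounds, stratum=strata.get("sigma")
    )
    dec_r = _truncated_normal(
        rng, p.decenter_r_mean, p.decenter_r_sd, p.decenter_r_bounds,
        stratum=strata.get("dec_r"),
    )
    dec_a = math.radians(
        rng.normal(p.decenter_angle_mean_deg, p.decenter_angle_sd_deg)
    )
    base_k = (
        _truncated_normal(rng, p.base_k_mean, p.base_k_sd, (p.base_k_mean - 4, p.base_k_mean + 4))
        + p.base_k_sphere_slope * (sph_t - p.sphere_mean) * 0.5
    )
    base_c = base_k / _KD

    eye = template_normal_eye(anterior_radius_mm=1.0 / base_c, anterior_conic=conic)
    eye.label = "keratoconus"
    eye.axial_length_bracket_mm = p.axial_length_bracket_mm
    eye.cone = ConeParams(
        center_x_mm=dec_r * math.cos(dec_a),
        center_y_mm=dec_r * math.sin(dec_a),
        amplitude_um=1.0,
        sigma_mm=sigma,
    )

    _solve_cone_amplitude(eye, kmax_t)
    # astigmatic target: keep the cone-induced axis, scale to the cylinder
    j_cone = _measure(eye)[1:]
    jmag = np.linalg.norm(j_cone)
    if jmag > 0.15:
        e_hat = j_cone / jmag
    else:
        two_ax = math.radians(2.0 * axis_t)
        e_hat = np.array([math.cos(two_ax), math.sin(two_ax)])
    target_j = (abs(cyl_t) / 2.0) * e_hat
    # alternate the two solves; finish on toricity (the cylinder tolerance
    # is much tighter than the Kmax one relative to the cohort SDs)
    _solve_toricity(eye, target_j, base_c)
    _solve_cone_amplitude(eye, kmax_t)
    _solve_toricity(eye, target_j, base_c, tol=0.04)
    _solve_vitreous(eye, sph_t)
    return eye


def generate_eye(
    rng_seed, cohort: str, params: Optional[CohortParams] = None, strata=None
) -> EyeBiometry:
    """Generate one synthetic eye; deterministic in seed and configuration.

    ``rng_seed`` may be an integer seed or a ``numpy.random.Generator``.
    Normal eyes are redrawn until the traced Seidel sphere satisfies the
    +/-10 D inclusion rule (guaranteed by target sampling, re-verified on
    the traced eye); solver failures trigger a redraw up to
    ``params.max_attempts``.
    """
    p = params or default_params(cohort)
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    last_err = None
    for _ in range(p.max_attempts):
        try:
            if cohort == "normal":
                eye = _generate_normal(rng, p, strata)
                m = _measure(eye)[0]
                if abs(m) > 10.0 + 1e-6:
                    raise GeneratorError(f"normal eye outside +/-10 D ({m:.2f})")
            elif cohort == "keratoconus":
                eye = _generate_keratoconus(rng, p, strata)
            else:
                raise ValueError(f"unknown cohort {cohort!r}")
            lo, hi = p.axial_length_bracket_mm
            if not (lo <= eye.axial_length_mm <= hi):
                raise GeneratorError(
                    f"axial length {eye.axial_length_mm:.2f} outside [{lo}, {hi}] mm"
                )
            return eye
        except (GeneratorError, ValueError) as err:  # includes bracket failures
            if isinstance(err, ValueError) and "cohort" in str(err):
                raise
            last_err = err
    raise GeneratorError(
        f"could not generate a valid {cohort} eye in {p.max_attempts} attempts: {last_err}"
    )


def generate_cohort(
    n: int, cohort: str, seed: int, params: Optional[CohortParams] = None
) -> list:
    """Generate ``n`` eyes with independent child seeds derived from ``seed``.

    Target quantities (Kmax, sphere, cylinder) are sampled with stratified
    inverse-CDF draws over independently permuted strata, so cohort means
    sit at the configured values while eyes stay exchangeable."""
    master = np.random.default_rng(np.random.SeedSequence(seed))
    quantities = ("kmax", "sphere", "cyl", "conic", "sigma", "dec_r")
    perms = {q: master.permutation(n) for q in quantities}
    seqs = np.random.SeedSequence(seed).spawn(n)
    eyes = []
    for i, s in enumerate(seqs):
        strata = {q: (int(perms[q][i]), n) for q in perms}
        eyes.append(generate_eye(np.random.default_rng(s), cohort, params, strata))
    return eyes
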