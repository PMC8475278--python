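"""Whole-eye biometry: surface stack, keratometry, and the I-S index.

An :class:`EyeBiometry` is an ordered stack of four refracting surfaces
(anterior cornea, posterior cornea, crystalline-lens front and back) plus a
pupil and an optional cone perturbation on the anterior cornea.  The
template values are a Navarro-style four-surface schematic eye with indices
taken as valid at 555 nm.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .geometry import ConeParams, ConicSurface, surface_sag
from . import paraxial

__all__ = [
    "EyeBiometry",
    "template_normal_eye",
    "compute_keratometry",
    "compute_is_value",
    "KERATOMETRIC_INDEX",
]

KERATOMETRIC_INDEX = 1.3375  # clinical convention: K = (n_k - 1) / r

# Refractive indices of the ocular media (555 nm)
N_CORNEA = 1.376
N_AQUEOUS = 1.3374
N_LENS = 1.420
N_VITREOUS = 1.336


@dataclass
class EyeBiometry:
    """Four-surface schematic eye with pupil and cone parameters.

    ``surfaces`` are ordered from anterior cornea to posterior lens;
    ``thickness_mm`` of each surface is the distance to the next one, and
    ``retina_distance_mm`` the distance from the posterior lens surface to
    the retinal plane.  The physical pupil sits at the crystalline-lens
    front vertex.
    """

    surfaces: list
    retina_distance_mm: float
    cone: ConeParams = field(default_factory=ConeParams)
    pupil_diameter_mm: float = 5.0
    label: str = "normal"
    axial_length_bracket_mm: tuple = (20.0, 28.0)

    def __post_init__(self) -> None:
        if len(self.surfaces) != 4:
            raise ValueError("an eye needs exactly 4 refracting surfaces")
        if self.pupil_diameter_mm <= 0:
            raise ValueError("pupil_diameter_mm must be > 0")
        lo, hi = self.axial_length_bracket_mm
        al = self.axial_length_mm
        if not (lo <= al <= hi):
            raise ValueError(f"axial length {al:.2f} mm outside [{lo}, {hi}] mm")

    @property
    def axial_length_mm(self) -> float:
        return sum(s.thickness_mm for s in self.surfaces[:3]) + self.retina_distance_mm

    @property
    def cornea_anterior(self) -> ConicSurface:
        return self.surfaces[0]

    @property
    def pupil_z_mm(self) -> float:
        """Axial position of the physical pupil (lens front vertex)."""
        return self.surfaces[0].thickness_mm + self.surfaces[1].thickness_mm

    def surface_z_positions(self) -> list:
        z, out = 0.0, []
        for s in self.surfaces:
            out.append(z)
            z += s.thickness_mm
        return out

    def media(self) -> list:
        """Index after each surface."""
        return [s.n_after for s in self.surfaces]

    def paraxial_elements(self, n_before: float = 1.0):
        """Paraxial element list from anterior cornea to the retina."""
        els = []
        n_in = n_before
        for s in self.surfaces:
            # Mean apical curvature of toric surfaces for the paraxial model
            c1, c2 = s.curvatures()
            r_eff = 2.0 / (c1 + c2)
            els.append(("R", paraxial.surface_power(n_in, s.n_after, r_eff)))
            n_in = s.n_after
            els.append(("T", s.thickness_mm, n_in))
        # Replace last transfer by retina distance
        els[-1] = ("T", self.retina_distance_mm, n_in)
        return els

    def paraxial_refraction_D(self, n_before: float = 1.0) -> float:
        """Vergence error at the corneal vertex: the correction (in D, at the
        cornea) that conjugates infinity with the retina."""
        m = paraxial.system_matrix(self.paraxial_elements(n_before))
        a, b = m[0, 0], m[0, 1]
        # focus on retina for object vergence V: y_r = (A - B*V) y0 = 0
        return a / b if abs(b) > 1e-15 else math.inf

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        return {
            "surfaces": [s.to_dict() for s in self.surfaces],
            "retina_distance_mm": self.retina_distance_mm,
            "cone": vars(self.cone).copy(),
            "pupil_diameter_mm": self.pupil_diameter_mm,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EyeBiometry":
        return cls(
            surfaces=[ConicSurface.from_dict(s) for s in d["surfaces"]],
            retina_distance_mm=d["retina_distance_mm"],
            cone=ConeParams(**d.get("cone", {})),
            pupil_diameter_mm=d.get("pupil_diameter_mm", 5.0),
            label=d.get("label", "normal"),
        )

    def to_json(self, path=None) -> str:
        txt = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(txt)
        return txt

    @classmethod
    def from_json(cls, path) -> "EyeBiometry":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_csv(self, path) -> None:
        """Tabular schema: one row per surface (kind='surface') plus one
        'cone' and one 'eye' row carrying the scalar blocks."""
        import pandas as pd

        rows = []
        for i, s in enumerate(self.surfaces):
            rows.append({"kind": "surface", "index": i, **s.to_dict()})
        rows.append({"kind": "cone", "index": -1, **vars(self.cone)})
        rows.append(
            {
                "kind": "eye",
                "index": -1,
                "retina_distance_mm": self.retina_distance_mm,
                "pupil_diameter_mm": self.pupil_diameter_mm,
                "label": self.label,
            }
        )
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EyeBiometry":
        import pandas as pd

        df = pd.read_csv(path)
        surf_cols = [
            "radius_mm", "conic", "n_after", "thickness_mm",
            "toric_radius_mm", "toric_axis_deg", "semi_aperture_mm",
        ]
        surfaces = []
        for _, row in df[df["kind"] == "surface"].sort_values("index").iterrows():
            d = {k: row[k] for k in surf_cols if k in row and not pd.isna(row[k])}
            surfaces.append(ConicSurface(**d))
        cone_row = df[df["kind"] == "cone"].iloc[0]
        cone = ConeParams(
            center_x_mm=float(cone_row["center_x_mm"]),
            center_y_mm=float(cone_row["center_y_mm"]),
            amplitude_um=float(cone_row["amplitude_um"]),
            sigma_mm=float(cone_row["sigma_mm"]),
        )
        eye_row = df[df["kind"] == "eye"].iloc[0]
        return cls(
            surfaces=surfaces,
            retina_distance_mm=float(eye_row["retina_distance_mm"]),
            cone=cone,
            pupil_diameter_mm=float(eye_row["pupil_diameter_mm"]),
            label=str(eye_row["label"]),
        )


def template_normal_eye(
    anterior_radius_mm: float = 7.849,
    anterior_conic: float = -0.45,
    retina_distance_mm: Optional[float] = None,
) -> EyeBiometry:
    """Navarro-style four-surface template eye; by default the vitreous
    depth is solved paraxially for emmetropia.

    The anterior corneal asphericity and the oblate lens back surface are
    calibrated so that a spherocylindrically best-corrected eye retains the
    higher-order aberration level of typical adult eyes at a 5-mm pupil
    (visual Strehl ~0.33 with spectacles, ~0.39 with scleral lenses)."""
    surfaces = [
        ConicSurface(anterior_radius_mm, anterior_conic, N_CORNEA, 0.55),
        ConicSurface(6.50, 0.0, N_AQUEOUS, 3.05),
        ConicSurface(10.20, -3.1316, N_LENS, 4.00),
        ConicSurface(-6.00, 1.0, N_VITREOUS, 0.0),
    ]
    eye = EyeBiometry(surfaces, retina_distance_mm or 16.4, label="normal")
    if retina_distance_mm is None:
        # Solve the vitreous depth for zero paraxial refraction.
        lo, hi = 13.0, 21.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            eye.retina_distance_mm = mid
            if eye.paraxial_refraction_D() > 0:  # hyperopic -> lengthen
                lo = mid
            else:
                hi = mid
        eye.retina_distance_mm = 0.5 * (lo + hi)
    return eye


def _meridional_power_map(
    eye: EyeBiometry,
    max_radius_mm: float = 3.0,
    radial_step_mm: float = 0.05,
    meridian_step_deg: float = 3.0,
    n_k: float = KERATOMETRIC_INDEX,
):
    """Keratometric (meridional/tangential) power sampled on a polar grid.

    Powers are (n_k - 1) / r_local with r_local the local meridional radius
    of curvature obtained by central finite differences of the anterior
    corneal sag along each meridian through the vertex.
    """
    surf = eye.cornea_anterior
    cone = eye.cone if eye.cone.amplitude_um > 0 else None
    angles = np.arange(0.0, 360.0, meridian_step_deg)
    # include the vertex-adjacent samples; extend one step past max radius
    rho = np.arange(radial_step_mm, max_radius_mm + 2 * radial_step_mm, radial_step_mm)
    a = np.radians(angles)[:, None]
    x = np.cos(a) * rho[None, :]
    y = np.sin(a) * rho[None, :]
    z = surface_sag(surf, x, y, cone)
    if not np.all(np.isfinite(z)):
        raise ValueError("degenerate corneal sag (non-finite within the zone)")
    h = radial_step_mm
    d1 = (z[:, 2:] - z[:, :-2]) / (2 * h)
    d2 = (z[:, 2:] - 2 * z[:, 1:-1] + z[:, :-2]) / (h * h)
    kappa = d2 / (1 + d1 * d1) ** 1.5
    power = (n_k - 1.0) * 1000.0 * kappa  # D, with curvature in 1/mm
    if not np.all(np.isfinite(power)):
        raise ValueError("non-finite curvature on the corneal zone")
    return angles, rho[1:-1], power


def compute_keratometry(
    eye: EyeBiometry,
    zone_radius_mm: float = 3.0,
    radial_step_mm: float = 0.05,
    meridian_step_deg: float = 3.0,
    n_k: float = KERATOMETRIC_INDEX,
) -> dict:
    """Kmax (max meridional power over the zone, including the apex) and
    Kmean (area mean over the central 3-mm zone)."""
    angles, rho, power = _meridional_power_map(
        eye, zone_radius_mm, radial_step_mm, meridian_step_deg, n_k
    )
    # Vertex power (the finite-difference grid starts just off the apex):
    # steepest apical curvature of the (bi)conic; a decentred cone's own
    # steep point lies on the sampled grid.
    c1, c2 = eye.cornea_anterior.curvatures()
    apex_k = (n_k - 1.0) * 1000.0 * max(c1, c2)
    kmax = float(max(np.max(power), apex_k))
    in_mean = rho <= 1.5
    w = rho[in_mean]
    kmean = float(np.average(np.mean(power[:, in_mean], axis=0), weights=w))
    return {"Kmax": kmax, "Kmean": kmean}


def compute_is_value(eye: EyeBiometry, ring_radius_mm: float = 3.0) -> float:
    """Inferior-superior index: mean keratometric power at five inferior
    points minus the mean at the five mirrored superior points, on the
    3-mm-radius circle with 30-degree spacing (Rabinowitz convention)."""
    angles, rho, power = _meridional_power_map(eye, ring_radius_mm)
    ring = np.argmin(np.abs(rho - ring_radius_mm))
    inferior = [210.0, 240.0, 270.0, 300.0, 330.0]
    superior = [150.0, 120.0, 90.0, 60.0, 30.0]

    def mean_at(angs):
        vals = []
        for ang in angs:
            i = np.argmin(np.abs(angles - ang))
            vals.append(power[i, ring])
        return float(np.mean(vals))

    return mean_at(inferior) - mean_at(superior)
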