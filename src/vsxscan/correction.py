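"""Spectacle and scleral-lens models for arbitrary spherocylindrical powers.

Fixed geometry of both modalities:

===========  ==========  ===========  ========  ==========  ===========
modality     post. R mm  lens index   thick mm  standoff    medium to eye
===========  ==========  ===========  ========  ==========  ===========
spectacle    100.0       1.510        2.000     12.000 mm   air (1.000)
scleral      7.20        1.415        0.300     0.325 mm    tears (1.3368)
===========  ==========  ===========  ========  ==========  ===========

The anterior surface is the variable one: its apical radius is solved per
meridian from the requested power, and it is made toric (biconic, shared
conic constant) for cylindrical prescriptions.  Conic constants are
-(1/n_corr) on the anterior surface and -(n_corr/n_following) on the
posterior surface.

Power conventions: spectacle powers are back-vertex powers measured in air
(the clinical lensmeter convention).  Scleral powers are labeled in situ -
as over-refraction relative to the neutral diagnostic lens on the template
eye (see ``SCLERAL_PLANO_OFFSET_D``) - so a "plano" scleral leaves a
template emmetrope emmetropic with the 0.325-mm tear layer in place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

from .geometry import ConicSurface
from .refraction import SpherocylRx

__all__ = ["CorrectionLens", "radius_for_power", "make_correction", "LENS_GEOMETRY"]

Modality = Literal["spectacle", "scleral"]

LENS_GEOMETRY = {
    "spectacle": dict(
        n_corr=1.510,
        posterior_radius_mm=100.0,
        center_thickness_mm=2.000,
        standoff_mm=12.000,
        pre_eye_medium_index=1.000,
        semi_aperture_mm=14.0,
    ),
    "scleral": dict(
        n_corr=1.415,
        posterior_radius_mm=7.20,
        center_thickness_mm=0.300,
        standoff_mm=0.325,
        pre_eye_medium_index=1.3368,
        semi_aperture_mm=7.0,
    ),
}

MAX_ABS_POWER_D = 30.0

# Scleral lens powers are labeled in situ, the way scleral prescriptions are
# ordered clinically: as over-refraction power relative to the neutral
# diagnostic lens.  The neutral (label "plano") lens is the one that leaves
# the emmetropic template eye emmetropic when worn; with the fixed 7.20-mm
# back surface and the 0.325-mm tear vault over the template cornea its
# back-vertex power measured in air is -4.325 D (the tear-lens
# compensation).  Labels map to air powers by adding this constant.
SCLERAL_PLANO_OFFSET_D = -4.3251


@dataclass
class CorrectionLens:
    """A correcting lens positioned in front of the eye.

    ``surfaces`` is [anterior, posterior]; the anterior surface's
    ``thickness_mm`` is the centre thickness and the posterior surface's
    ``thickness_mm`` is the standoff (vertex distance or vault) to the
    corneal apex.
    """

    modality: Modality
    surfaces: list
    rx: SpherocylRx

    @property
    def n_corr(self) -> float:
        return self.surfaces[0].n_after

    @property
    def pre_eye_medium_index(self) -> float:
        return self.surfaces[1].n_after

    @property
    def standoff_mm(self) -> float:
        return self.surfaces[1].thickness_mm

    @property
    def center_thickness_mm(self) -> float:
        return self.surfaces[0].thickness_mm

    def to_dict(self) -> dict:
        return {
            "modality": self.modality,
            "rx": vars(self.rx).copy(),
            "surfaces": [s.to_dict() for s in self.surfaces],
        }


def radius_for_power(target_back_vertex_power_D: float, modality: Modality) -> float:
    """Anterior apical radius (mm) giving the requested back-vertex power.

    Closed-form inversion of the thick-lens vertex-power relation
    ``P_bv = P2 + P1 / (1 - (t/n) P1)`` with the fixed posterior surface and
    thickness of the modality.
    """
    if abs(target_back_vertex_power_D) > MAX_ABS_POWER_D:
        raise ValueError(f"target power {target_back_vertex_power_D} D outside +/-{MAX_ABS_POWER_D} D")
    if modality == "scleral":
        target_back_vertex_power_D = target_back_vertex_power_D + SCLERAL_PLANO_OFFSET_D
    g = LENS_GEOMETRY[modality]
    n = g["n_corr"]
    tau = g["center_thickness_mm"] * 1e-3 / n
    p2 = (1.0 - n) / (g["posterior_radius_mm"] * 1e-3)
    q = target_back_vertex_power_D - p2
    p1 = q / (1.0 + tau * q)
    if abs(p1) < 1e-9:
        return 1e9  # effectively flat
    r1 = (n - 1.0) / p1 * 1e3
    if abs(r1) < 2.0:
        raise ValueError(f"infeasible prescription: anterior radius {r1:.3f} mm")
    return r1


def make_correction(rx: SpherocylRx, modality: Modality) -> CorrectionLens:
    """Build the lens for a prescription, centred on the optical axis.

    The meridian at ``axis_deg`` carries the sphere power and the
    perpendicular meridian sphere+cylinder (minus-cylinder convention).
    """
    rx = SpherocylRx.normalized(rx.sphere_D, rx.cylinder_D, rx.axis_deg)
    g = LENS_GEOMETRY[modality]
    n = g["n_corr"]
    r_axis = radius_for_power(rx.sphere_D, modality)
    conic_ant = -1.0 / n
    conic_post = -n / g["pre_eye_medium_index"]
    if abs(rx.cylinder_D) < 1e-12:
        anterior = ConicSurface(
            r_axis, conic_ant, n, g["center_thickness_mm"],
            semi_aperture_mm=g["semi_aperture_mm"],
        )
    else:
        r_cross = radius_for_power(rx.sphere_D + rx.cylinder_D, modality)
        anterior = ConicSurface(
            r_axis, conic_ant, n, g["center_thickness_mm"],
            toric_radius_mm=r_cross, toric_axis_deg=rx.axis_deg,
            semi_aperture_mm=g["semi_aperture_mm"],
        )
    posterior = ConicSurface(
        g["posterior_radius_mm"], conic_post, g["pre_eye_medium_index"],
        g["standoff_mm"], semi_aperture_mm=g["semi_aperture_mm"],
    )
    return CorrectionLens(modality=modality, surfaces=[anterior, posterior], rx=rx)
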