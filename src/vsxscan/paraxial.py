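"""Paraxial (2x2 system-matrix) optics.

Used as an independent oracle for the exact ray tracer, for solving lens
radii from vertex powers, and for locating entrance/exit pupils.  Matrices
act on (height y [m], reduced angle w = n*u) column vectors:

    refraction:  [[1, 0], [-P, 1]]        (P in diopters)
    transfer:    [[1, t/n], [0, 1]]       (t in meters)
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "refraction_matrix",
    "transfer_matrix",
    "surface_power",
    "system_matrix",
    "back_vertex_power",
    "image_of_plane",
]


def surface_power(n_before: float, n_after: float, radius_mm: float) -> float:
    """Dioptric power of a single refracting surface."""
    return (n_after - n_before) / (radius_mm * 1e-3)


def refraction_matrix(power_d: float) -> np.ndarray:
    return np.array([[1.0, 0.0], [-power_d, 1.0]])


def transfer_matrix(thickness_mm: float, n: float) -> np.ndarray:
    return np.array([[1.0, thickness_mm * 1e-3 / n], [0.0, 1.0]])


def system_matrix(elements) -> np.ndarray:
    """Product of elementary matrices.

    ``elements`` is an iterable of ("R", power_d) or ("T", thickness_mm, n)
    tuples given in the order light traverses them.
    """
    m = np.eye(2)
    for el in elements:
        if el[0] == "R":
            m = refraction_matrix(el[1]) @ m
        elif el[0] == "T":
            m = transfer_matrix(el[1], el[2]) @ m
        else:
            raise ValueError(f"unknown element {el!r}")
    return m


def back_vertex_power(
    radii_mm, thickness_mm: float, n_lens: float, n_before: float = 1.0, n_after: float = 1.0
) -> float:
    """Back-vertex power of a thick lens: output vergence (in the image
    medium) at the back vertex for an object at infinity."""
    r1, r2 = radii_mm
    m = system_matrix(
        [
            ("R", surface_power(n_before, n_lens, r1)),
            ("T", thickness_mm, n_lens),
            ("R", surface_power(n_lens, n_after, r2)),
        ]
    )
    # Parallel input (y0=1, w0=0) -> y = A, w = C; vergence = w/y * ... in
    # reduced form V = -C/A when measured as n*u / y.
    a, c = m[0, 0], m[1, 0]
    return -c / a  # w_out / y_out for parallel input


def image_of_plane(m: np.ndarray, n_image: float) -> tuple[float, float]:
    """Image of the object plane at a matrix's input plane.

    Given the system matrix ``m`` from the object plane to some reference
    output plane, returns (d_mm, magnification): the image lies ``d_mm``
    (signed, in mm) after the reference plane in a medium of index
    ``n_image``.
    """
    a, b = m[0, 0], m[0, 1]
    c, d = m[1, 0], m[1, 1]
    # Require total B' = (d'/n) * D + B = 0
    if abs(d) < 1e-15:
        raise ValueError("image at infinity")
    dist_m = -b * n_image / d
    mag = a + (dist_m / n_image) * c
    return dist_m * 1e3, mag
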