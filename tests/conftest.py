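import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

# property tests run derandomized so the suite is reproducible everywhere
hypothesis_settings.register_profile("det", derandomize=True, deadline=None)
hypothesis_settings.load_profile("det")

from vsxscan.eye import template_normal_eye
from vsxscan.raytrace import pupil_samples
from vsxscan.viq import VsxEngine


@pytest.fixture(scope="session")
def template_eye():
    return template_normal_eye()


@pytest.fixture(scope="session")
def engine():
    """Shared VSX engine (construction is the expensive part)."""
    return VsxEngine()


@pytest.fixture(scope="session")
def small_engine():
    """Reduced grid for fast through-focus sweeps in tests."""
    return VsxEngine(pupil_grid=128, pad_factor=2)


@pytest.fixture(scope="session")
def hex_samples():
    return pupil_samples()


@pytest.fixture(scope="session")
def perfect_eye():
    """Aberration-free fixture: a single Cartesian-oval refracting surface
    (conic k = -(1/n)^2 images axial infinity stigmatically); the remaining
    surface slots are index-matched planes that do not refract."""
    from vsxscan.eye import EyeBiometry
    from vsxscan.geometry import ConicSurface

    n = 1.336
    r = 6.0
    f = n * r / (n - 1.0)  # back focal distance from the surface vertex
    surfaces = [
        ConicSurface(r, -(1.0 / n) ** 2, n, 2.00),  # clear of the corneal sag
        ConicSurface(1e9, 0.0, n, 3.05),
        ConicSurface(1e9, 0.0, n, 4.00),
        ConicSurface(1e9, 0.0, n, 0.0),
    ]
    eye = EyeBiometry(
        surfaces,
        retina_distance_mm=f - 2.00 - 3.05 - 4.00,
        label="fixture",
        axial_length_bracket_mm=(5.0, 40.0),
    )
    return eye
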