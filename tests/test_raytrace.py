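import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vsxscan import paraxial
from vsxscan.eye import template_normal_eye
from vsxscan.geometry import ConicSurface
from vsxscan.raytrace import (
    TraceError,
    intersect_conic,
    pupil_samples,
    refract_ray,
    trace_system,
)
from vsxscan.zernike import fit_zernike


class TestPupilSampling:
    def test_121_rays_in_unit_disk(self):
        p = pupil_samples()
        assert p.shape == (121, 2)
        assert np.all(np.hypot(p[:, 0], p[:, 1]) <= 1.0 + 1e-12)
        assert np.allclose(p[0], 0.0)


class TestIntersectConic:
    def test_on_axis_hits_vertex(self):
        s = ConicSurface(7.8, -0.26, 1.376)
        pt, nrm, ok = intersect_conic([[0, 0, -5.0]], [[0, 0, 1.0]], s)
        assert ok[0]
        assert np.allclose(pt[0], [0, 0, 0], atol=1e-12)
        assert np.allclose(np.abs(nrm[0]), [0, 0, 1], atol=1e-12)

    @pytest.mark.parametrize(
        "conic,expected_sag",
        [(0.0, 7.8 - math.sqrt(7.8**2 - 4.0)), (-1.0, 4.0 / (2 * 7.8))],
    )
    def test_parallel_ray_sag(self, conic, expected_sag):
        s = ConicSurface(7.8, conic, 1.376)
        pt, _, ok = intersect_conic([[2.0, 0, -5.0]], [[0, 0, 1.0]], s)
        assert ok[0]
        assert pt[0, 2] == pytest.approx(expected_sag, abs=1e-10)

    def test_newton_matches_closed_form(self):
        """The damped-Newton path (used for toric/cone surfaces) agrees with
        the quadratic solution on a plain conic."""
        s = ConicSurface(7.8, -0.3, 1.376)
        s_toric = ConicSurface(7.8, -0.3, 1.376, toric_radius_mm=7.8, toric_axis_deg=10.0)
        p = [[1.5, -0.7, -4.0]]
        d = np.array([[0.05, 0.02, 1.0]])
        d = d / np.linalg.norm(d)
        pt1, _, ok1 = intersect_conic(p, d, s)
        pt2, _, ok2 = intersect_conic(p, d, s_toric)
        assert ok1[0] and ok2[0]
        assert np.allclose(pt1, pt2, atol=1e-9)

    def test_miss_is_flagged(self):
        s = ConicSurface(7.8, 0.0, 1.376, semi_aperture_mm=3.0)
        _, _, ok = intersect_conic([[5.0, 0, -5.0]], [[0, 0, 1.0]], s)
        assert not ok[0]


class TestRefractRay:
    def test_index_match_is_identity(self):
        d = np.array([[0.3, 0.1, 0.94]])
        d = d / np.linalg.norm(d)
        out, ok = refract_ray(d, [[0, 0, 1.0]], 1.336, 1.336)
        assert ok[0]
        assert np.allclose(out, d, atol=1e-14)

    def test_snell_scalar_check(self):
        """30 degrees incidence from air into n=1.5: refraction angle
        arcsin(0.5/1.5) = 19.471 degrees."""
        inc = math.radians(30.0)
        d = [[math.sin(inc), 0.0, math.cos(inc)]]
        out, ok = refract_ray(d, [[0, 0, -1.0]], 1.0, 1.5)
        assert ok[0]
        angle = math.degrees(math.asin(out[0, 0]))
        assert angle == pytest.approx(19.4712, abs=1e-3)

    def test_total_internal_reflection_flagged(self):
        inc = math.radians(80.0)
        d = [[math.sin(inc), 0.0, math.cos(inc)]]
        _, ok = refract_ray(d, [[0, 0, 1.0]], 1.5, 1.0)
        assert not ok[0]

    @settings(max_examples=30, deadline=None)
    @given(
        theta=st.floats(0.01, 0.9),
        phi=st.floats(0.0, 2 * math.pi),
        n1=st.floats(1.0, 1.6),
        n2=st.floats(1.0, 1.6),
    )
    def test_reversibility(self, theta, phi, n1, n2):
        """Reversing a refracted ray through the same interface recovers
        the incident direction."""
        d = np.array([[math.sin(theta) * math.cos(phi), math.sin(theta) * math.sin(phi), math.cos(theta)]])
        n = np.array([[0.0, 0.0, 1.0]])
        out, ok = refract_ray(d, n, n1, n2)
        if not ok[0]:
            return
        back, ok2 = refract_ray(-out, n, n2, n1)
        assert ok2[0]
        assert np.allclose(back, -d, atol=1e-10)


class TestTraceSystem:
    def test_stigmatic_fixture_has_zero_opd(self, perfect_eye):
        """A Cartesian-oval eye focuses infinity perfectly: OPD = 0."""
        tr = trace_system(perfect_eye)
        assert tr.n_lost == 0
        assert np.nanmax(np.abs(tr.opd_um)) < 1e-6

    def test_chief_ray_opd_zero(self, template_eye):
        tr = trace_system(template_eye)
        assert tr.opd_um[0] == 0.0

    def test_ray_count_conserved(self, template_eye):
        tr = trace_system(template_eye)
        assert int(tr.valid.sum()) + tr.n_lost == 121

    def test_defocus_matches_paraxial_oracle(self):
        """An axially elongated template eye shows the defocus predicted by
        the paraxial matrix model (via the Seidel/paraxial match)."""
        eye = template_normal_eye()
        eye.retina_distance_mm += 0.5
        from vsxscan.pipeline import analyze_eye

        an = analyze_eye(eye)
        assert an.seidel_rx.sphere_D == pytest.approx(
            eye.paraxial_refraction_D(), abs=0.08
        )

    def test_sampling_sufficiency(self, template_eye):
        """Tripling the ray density changes fitted coefficients by < 1% RMS."""
        from vsxscan.raytrace import _HEXAPOLAR_RINGS

        tr1 = trace_system(template_eye)
        w1 = fit_zernike(tr1.pupil_xy_norm[:, 0], tr1.pupil_xy_norm[:, 1], tr1.opd_um, 2.5)
        dense = [(0.0, 0.0)]
        n_rings = 10
        for i in range(1, n_rings + 1):
            r = i / n_rings
            m = 8 * i
            ang = 2 * np.pi * np.arange(m) / m
            dense.extend(zip(r * np.cos(ang), r * np.sin(ang)))
        tr2 = trace_system(template_eye, samples_norm=np.array(dense))
        w2 = fit_zernike(tr2.pupil_xy_norm[:, 0], tr2.pupil_xy_norm[:, 1], tr2.opd_um, 2.5)
        num = np.linalg.norm(w1.metric_coeffs - w2.metric_coeffs)
        den = np.linalg.norm(w2.metric_coeffs)
        assert num / den < 0.01

    def test_corrected_eye_flattens_wavefront(self, template_eye):
        """The eye's own best spectacle shrinks the peak-to-valley OPD."""
        from vsxscan.correction import make_correction
        from vsxscan.pipeline import analyze_eye

        an = analyze_eye(template_eye)
        lens = make_correction(an.zernike_rx, "spectacle")
        tr0 = trace_system(template_eye)
        tr1 = trace_system(template_eye, lens)
        ptv0 = np.nanmax(tr0.opd_um) - np.nanmin(tr0.opd_um)
        ptv1 = np.nanmax(tr1.opd_um) - np.nanmin(tr1.opd_um)
        assert ptv1 < ptv0

    def test_unphysical_configuration_raises(self, template_eye):
        samples = pupil_samples() * 2.5  # far outside the aperture
        samples[0] = 0.0
        with pytest.raises(TraceError):
            trace_system(template_eye, samples_norm=samples, max_loss_fraction=0.05)


class TestParaxialOracle:
    def test_thin_lens_focal_matrix(self):
        m = paraxial.system_matrix([("R", 60.0), ("T", 1000.0 / 60.0, 1.0)])
        # parallel ray crosses the axis at the focal plane
        y, w = m @ np.array([1.0, 0.0])
        assert y == pytest.approx(0.0, abs=1e-12)

    def test_back_vertex_power_identity(self):
        p = paraxial.back_vertex_power((100.0, -100.0), 2.0, 1.5)
        # thick biconvex: P1 + P2 + t/n P1 P2 corrections
        p1 = (1.5 - 1) / 0.1
        p2 = (1 - 1.5) / -0.1
        expected = p2 + p1 / (1 - 0.002 / 1.5 * p1)
        assert p == pytest.approx(expected, abs=1e-9)
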