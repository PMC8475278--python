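import math

import numpy as np
import pytest

from vsxscan.viq import (
    NeuralWeight,
    PsfGrid,
    VsxEngine,
    neural_weight_profile,
    render_chart,
    tumbling_e_chart,
    vsx,
)
from vsxscan.zernike import WavefrontCoefficients, osa_index


def wf(d=None, r=2.5):
    c = np.zeros(45)
    for (n, m), v in (d or {}).items():
        c[osa_index(n, m)] = v
    return WavefrontCoefficients(c, r)


def defocus_um(diopters, r=2.5):
    return diopters * r**2 / (4 * math.sqrt(3))


class TestPsf:
    def test_airy_first_zero(self):
        """Zero wavefront gives the Airy pattern with its first dark ring at
        1.22 lambda/D = 0.4656 arcmin for a 5-mm pupil at 555 nm."""
        eng = VsxEngine(pupil_grid=128, pad_factor=8)
        psf = eng.psf(wf())
        iy, ix = psf.peak_index
        prof = psf.intensity[iy, ix:]
        mins = [i for i in range(1, 25) if prof[i] < prof[i - 1] and prof[i] <= prof[i + 1]]
        assert mins, "no dark ring found"
        r_first = mins[0] * psf.pixel_scale_arcmin
        expected = math.degrees(1.22 * 0.555e-3 / 5.0) * 60.0
        assert r_first == pytest.approx(expected, abs=1.5 * psf.pixel_scale_arcmin)

    def test_unit_sum_normalization(self, small_engine):
        psf = small_engine.psf(wf({(3, -1): 0.4}))
        assert np.sum(psf.intensity) == pytest.approx(1.0, rel=1e-6)

    def test_through_focus_strehl_ordering(self, small_engine):
        """0.25 D of defocus sits strictly between 0 and 0.50 D."""
        v0 = small_engine.vsx(wf())
        v1 = small_engine.vsx(wf({(2, 0): defocus_um(0.25)}))
        v2 = small_engine.vsx(wf({(2, 0): defocus_um(0.50)}))
        assert v0 > v1 > v2

    def test_aliasing_check(self):
        eng = VsxEngine(pupil_grid=64, pad_factor=2)
        with pytest.raises(ValueError):
            eng.psf(wf({(2, 0): defocus_um(8.0)}), check=True)


class TestNeuralWeight:
    def test_peak_normalized_and_decreasing(self, engine):
        nw = engine.neural_weight()
        n = nw.weights.shape[0]
        center = nw.weights[n // 2, n // 2]
        assert center == pytest.approx(1.0, abs=1e-6)
        profile = nw.weights[n // 2, n // 2 :]
        lim = int(10.0 / nw.pixel_scale_arcmin)
        assert np.all(np.diff(profile[:lim]) <= 0)

    def test_closed_form_profile(self):
        r = np.array([0.0, 1.0, 3.0])
        w = neural_weight_profile(r, 7.0)
        x = 2 * math.pi * 7.0 * r / 60.0
        assert np.allclose(w, (1 + x**2) ** -1.5)

    def test_finite_positive_area(self, engine):
        nw = engine.neural_weight()
        total = float(np.sum(nw.weights)) * nw.pixel_scale_arcmin**2
        assert np.isfinite(total) and total > 0


class TestVsx:
    def test_diffraction_limited_is_one(self, engine):
        assert engine.vsx(wf()) == pytest.approx(1.0, abs=1e-9)

    def test_piston_and_tilt_invariance(self, engine):
        """Piston and tilt carry no image-quality information: VSX is
        unchanged (tilt only translates the PSF, and the weighting follows
        the peak)."""
        v0 = engine.vsx(wf({(2, 0): 0.3}))
        v1 = engine.vsx(wf({(0, 0): 5.0, (1, 1): 2.0, (1, -1): -1.0, (2, 0): 0.3}))
        assert v1 == pytest.approx(v0, abs=1e-9)

    def test_vsx_in_unit_interval(self, small_engine):
        rng = np.random.default_rng(5)
        for _ in range(5):
            c = np.zeros(45)
            c[3:] = rng.normal(0, 0.15, 42)
            v = small_engine.vsx(WavefrontCoefficients(c, 2.5))
            assert 0.0 < v <= 1.0 + 1e-9

    def test_monotone_defocus_sweep(self, small_engine):
        """VSX strictly decreases along a pure-defocus sweep 0 -> 1 D."""
        vals = [
            small_engine.vsx(wf({(2, 0): defocus_um(d)}))
            for d in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_grid_resolution_robustness(self, template_eye):
        """Doubling the PSF grid changes template-eye VSX by < 1%."""
        from vsxscan.pipeline import analyze_eye

        an = analyze_eye(template_eye)
        v1 = VsxEngine(pupil_grid=128, pad_factor=2).vsx(an.wavefront)
        v2 = VsxEngine(pupil_grid=256, pad_factor=2).vsx(an.wavefront)
        assert v2 == pytest.approx(v1, rel=0.01)

    def test_far_defocus_stays_below_ladder_thresholds(self):
        """Far from focus the pupil grid undersamples the wavefront, but
        the VSX it reports stays well below the 0.03/0.01 scan thresholds,
        so out-of-range evaluations can never seed scan refinement."""
        eng = VsxEngine(pupil_grid=192, pad_factor=2)
        for d in (4.0, 8.0, 12.0, 18.0):
            assert eng.vsx(wf({(2, 0): defocus_um(d)})) < 0.008
        for d in (6.0, 12.0):
            c = d * 2.5**2 / (4 * math.sqrt(6))
            assert eng.vsx(wf({(2, 2): c})) < 0.008

    def test_functional_api_matches_engine(self, small_engine):
        w = wf({(2, 0): 0.2, (3, 1): 0.1})
        psf = small_engine.psf(w)
        ref = small_engine.psf(wf())
        nw = small_engine.neural_weight()
        assert vsx(psf, nw, ref) == pytest.approx(small_engine.vsx(w), rel=1e-6)


class TestChartRendering:
    def test_delta_psf_identity(self):
        k = np.zeros((31, 31), dtype=float)
        k[15, 15] = 1.0
        psf = PsfGrid(k, 0.25)
        chart = tumbling_e_chart((0.3, 0.0), pixel_scale_arcmin=0.25)
        out = render_chart(psf, chart, 0.25)
        assert np.allclose(out, chart, atol=1e-9)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        k = rng.uniform(0, 1, (15, 15))
        psf = PsfGrid(k / k.sum(), 0.25)
        chart = tumbling_e_chart((0.2,), pixel_scale_arcmin=0.25)
        out1 = render_chart(psf, chart, 0.25)
        out2 = render_chart(psf, 3.0 * chart, 0.25)
        assert np.allclose(out2, 3.0 * out1, atol=1e-9)

    def test_blur_reduces_contrast(self, small_engine):
        """A wider (more defocused) PSF lowers the RMS contrast of the
        rendered chart."""
        chart = tumbling_e_chart((0.4, 0.1), pixel_scale_arcmin=small_engine.pixel_scale_arcmin)
        outs = []
        for d in (0.1, 0.6):
            psf = small_engine.psf(wf({(2, 0): defocus_um(d)}))
            out = render_chart(psf, chart, small_engine.pixel_scale_arcmin)
            outs.append(np.std(out) / np.mean(out))
        assert outs[1] < outs[0]

    def test_scale_mismatch_raises(self):
        psf = PsfGrid(np.ones((9, 9)) / 81.0, 0.25)
        with pytest.raises(ValueError):
            render_chart(psf, np.ones((20, 20)), 0.5)
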