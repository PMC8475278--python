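import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vsxscan.raytrace import pupil_samples
from vsxscan.refraction import (
    PowerVector,
    SpherocylRx,
    power_vector_to_rx,
    rx_to_power_vector,
    seidel_refraction,
    zernike_refraction,
)
from vsxscan.zernike import (
    WavefrontCoefficients,
    fit_zernike,
    osa_index,
    osa_nm,
    rescale_coefficients,
    zernike_basis,
)


def coeffs_with(d):
    c = np.zeros(45)
    for (n, m), v in d.items():
        c[osa_index(n, m)] = v
    return c


class TestZernikeBasis:
    def test_osa_indexing_roundtrip(self):
        for j in range(45):
            n, m = osa_nm(j)
            assert osa_index(n, m) == j
            assert (n - abs(m)) % 2 == 0 and abs(m) <= n

    def test_orthonormality(self):
        """ANSI normalization: <Z_i Z_j> over the unit disk = delta_ij."""
        n = 512
        g = (np.arange(n) + 0.5) / n * 2 - 1
        gx, gy = np.meshgrid(g, g)
        mask = gx**2 + gy**2 <= 1
        b = zernike_basis(gx[mask], gy[mask], 6)
        gram = (b.T @ b) / mask.sum()
        assert np.allclose(gram, np.eye(b.shape[1]), atol=5e-3)


class TestFitZernike:
    def test_single_mode_identity(self, hex_samples):
        """OPD equal to one mode (c4^0 = 0.5 um) on the 121-ray pattern is
        recovered exactly with all other terms < 1e-6."""
        c = coeffs_with({(4, 0): 0.5})
        w = zernike_basis(hex_samples[:, 0], hex_samples[:, 1], 8) @ c
        fit = fit_zernike(hex_samples[:, 0], hex_samples[:, 1], w, 2.5)
        assert fit.c(4, 0) == pytest.approx(0.5, abs=1e-6)
        others = fit.coeffs.copy()
        others[osa_index(4, 0)] = 0.0
        assert np.max(np.abs(others)) < 1e-6

    def test_random_combination_roundtrip(self, hex_samples):
        rng = np.random.default_rng(7)
        c = rng.normal(0, 0.4, 45)
        w = zernike_basis(hex_samples[:, 0], hex_samples[:, 1], 8) @ c
        fit = fit_zernike(hex_samples[:, 0], hex_samples[:, 1], w, 2.5)
        assert np.max(np.abs(fit.coeffs - c)) < 1e-6

    def test_fit_is_projection(self, hex_samples):
        """Fitting the fit's reconstruction returns identical coefficients."""
        rng = np.random.default_rng(11)
        w = rng.normal(0, 1.0, len(hex_samples))  # arbitrary non-polynomial data
        f1 = fit_zernike(hex_samples[:, 0], hex_samples[:, 1], w, 2.5)
        recon = zernike_basis(hex_samples[:, 0], hex_samples[:, 1], 8) @ f1.coeffs
        f2 = fit_zernike(hex_samples[:, 0], hex_samples[:, 1], recon, 2.5)
        assert np.allclose(f1.coeffs, f2.coeffs, atol=1e-9)

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError):
            fit_zernike([0.0] * 50, [0.0] * 50, [0.0] * 50, 2.5)

    def test_clustered_samples_raise(self):
        x = np.full(100, 0.3)
        y = np.linspace(-0.5, 0.5, 100)
        with pytest.raises(ValueError):
            fit_zernike(x, y, np.zeros(100), 2.5)


class TestRescaling:
    def test_defocus_scaling_closed_form(self):
        """Pure defocus rescaled from 3.0- to 2.5-mm radius scales by
        (2.5/3.0)^2 = 0.6944."""
        w = WavefrontCoefficients(coeffs_with({(2, 0): 1.0}), 3.0)
        w2 = rescale_coefficients(w, 2.5)
        assert w2.c(2, 0) == pytest.approx((2.5 / 3.0) ** 2, abs=1e-9)

    def test_rescale_preserves_wavefront_values(self):
        rng = np.random.default_rng(3)
        c = rng.normal(0, 0.2, 45)
        w = WavefrontCoefficients(c, 3.0)
        w2 = rescale_coefficients(w, 2.0)
        # evaluate both on the same physical points (r <= 2 mm)
        pts = rng.uniform(-0.6, 0.6, (50, 2))
        b_old = zernike_basis(pts[:, 0] * 2.0 / 3.0, pts[:, 1] * 2.0 / 3.0, 8)
        b_new = zernike_basis(pts[:, 0], pts[:, 1], 8)
        assert np.allclose(b_old @ w.coeffs, b_new @ w2.coeffs, atol=1e-9)


class TestCoefficientSerialization:
    def test_csv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(9)
        w = WavefrontCoefficients(rng.normal(0, 0.3, 45), 2.787)
        path = tmp_path / "coeffs.csv"
        w.to_csv(path)
        back = WavefrontCoefficients.from_csv(path)
        assert back.pupil_radius_mm == w.pupil_radius_mm
        assert np.allclose(back.coeffs, w.coeffs, atol=0)


class TestRefractionFormulas:
    def test_plano_for_zero_wavefront(self):
        w = WavefrontCoefficients(np.zeros(45), 2.5)
        rx = zernike_refraction(w)
        assert rx == SpherocylRx(0.0, 0.0, 0.0)

    def test_defocus_formula(self):
        """c2^0 = 1 um at r = 2.5 mm: M = -4 sqrt(3) / 6.25 = -1.1085 D."""
        w = WavefrontCoefficients(coeffs_with({(2, 0): 1.0}), 2.5)
        pv = rx_to_power_vector(zernike_refraction(w))
        assert pv.M == pytest.approx(-4 * math.sqrt(3) / 6.25, abs=1e-9)

    def test_pure_c22_axis(self):
        w = WavefrontCoefficients(coeffs_with({(2, 2): 0.5}), 2.5)
        rx = zernike_refraction(w)
        pv = rx_to_power_vector(rx)
        assert pv.J45 == pytest.approx(0.0, abs=1e-12)
        assert rx.axis_deg in (0.0, 90.0)

    def test_seidel_reduces_to_zernike(self):
        c = coeffs_with({(2, 0): 0.8, (2, 2): -0.3, (2, -2): 0.1})
        w = WavefrontCoefficients(c, 2.5)
        assert seidel_refraction(w) == zernike_refraction(w)

    def test_seidel_spherical_chain(self):
        """c4^0 = 0.1 um shifts Seidel M by +12 sqrt(5) * 0.1 / 6.25."""
        w1 = WavefrontCoefficients(coeffs_with({(2, 0): 1.0}), 2.5)
        w2 = WavefrontCoefficients(coeffs_with({(2, 0): 1.0, (4, 0): 0.1}), 2.5)
        m1 = rx_to_power_vector(seidel_refraction(w1)).M
        m2 = rx_to_power_vector(seidel_refraction(w2)).M
        assert m2 - m1 == pytest.approx(12 * math.sqrt(5) * 0.1 / 6.25, abs=1e-9)

    def test_seidel_curvature_matches_wavefront_slope(self):
        """The Seidel M equals the r^2 content of the wavefront near the
        pupil centre (finite-difference curvature oracle)."""
        c = coeffs_with({(2, 0): 0.7, (4, 0): 0.12, (6, 0): -0.03})
        w = WavefrontCoefficients(c, 2.5)
        m = rx_to_power_vector(seidel_refraction(w)).M
        # independent oracle: the exact h^2 coefficient of the radial
        # wavefront profile W(h) [um, h in mm]; a defocus of power P has
        # W = -(P/2) h^2 in these units, so M = -2 * a2
        rho = np.linspace(0, 0.5, 41)
        vals = zernike_basis(rho, np.zeros_like(rho), 8) @ c
        a2 = np.polyfit(rho * 2.5, vals, 8)[-3]  # um per mm^2
        assert m == pytest.approx(-2.0 * a2, abs=1e-6)

    def test_astigmatic_higher_switch(self):
        c = coeffs_with({(2, 2): 0.5, (4, 2): 0.1})
        w = WavefrontCoefficients(c, 2.5)
        with_h = rx_to_power_vector(seidel_refraction(w, include_astigmatic_higher=True))
        without = rx_to_power_vector(seidel_refraction(w, include_astigmatic_higher=False))
        assert with_h.J0 - without.J0 == pytest.approx(6 * math.sqrt(10) * 0.1 / 6.25, abs=1e-9)


class TestPowerVectors:
    def test_printed_example(self):
        pv = rx_to_power_vector(SpherocylRx(-11.5, -7.25, 177.5))
        assert pv.M == pytest.approx(-15.125, abs=1e-3)
        assert pv.J0 == pytest.approx(3.611, abs=1e-3)
        assert pv.J45 == pytest.approx(-0.316, abs=1e-3)

    def test_plano(self):
        pv = rx_to_power_vector(SpherocylRx(0.0, 0.0, 0.0))
        assert (pv.M, pv.J0, pv.J45) == (0.0, 0.0, 0.0)

    @settings(max_examples=200, deadline=None)
    @given(
        s=st.floats(-20, 20),
        c=st.floats(-15, 0),
        a=st.floats(0, 179.99),
    )
    def test_roundtrip_property(self, s, c, a):
        rx = SpherocylRx.normalized(s, c, a)
        back = power_vector_to_rx(rx_to_power_vector(rx))
        assert back.sphere_D == pytest.approx(rx.sphere_D, abs=1e-9)
        assert back.cylinder_D == pytest.approx(rx.cylinder_D, abs=1e-9)
        if abs(rx.cylinder_D) > 1e-9:
            diff = abs(back.axis_deg - rx.axis_deg) % 180.0
            assert min(diff, 180.0 - diff) < 1e-6

    def test_transposition_identity(self):
        rx = SpherocylRx.normalized(-3.5, 1.5, 180.0)
        assert rx == SpherocylRx.normalized(-2.0, -1.5, 90.0)

    def test_string_parsing(self):
        rx = SpherocylRx.from_string("-2.00 -1.50 x 90")
        assert rx == SpherocylRx(-2.0, -1.5, 90.0)
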