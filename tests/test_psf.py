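import math

import numpy as np
import pytest

from scarres import psf
from scarres.psf import (
    PAPER_RESOLUTIONS_MM,
    FilterDesign,
    ResolutionSpec,
    apply_lowpass,
    calibrate_filter,
    measure_psf_fwhm,
)

SPEC = ResolutionSpec()  # 128 @ 0.7 mm


def brute_force_circular_convolution(image, kfilter):
    """Spatial-domain oracle: circular convolution with the PSF of the
    centered k-space filter, computed with explicit loops."""
    n = image.shape[0]
    psf_img = np.fft.ifft2(np.fft.ifftshift(kfilter))
    out = np.zeros_like(image, dtype=complex)
    for i in range(n):
        for j in range(n):
            acc = 0.0 + 0.0j
            for di in range(n):
                for dj in range(n):
                    acc += image[(i - di) % n, (j - dj) % n] * psf_img[di, dj]
            out[i, j] = acc
    return out


class TestMeasureFwhm:
    def test_matches_continuous_gaussian_closed_form(self):
        # FT of a Gaussian is Gaussian: FWHM_x = 2 sqrt(2 ln 2) / (2 pi sigma_k)
        sigma_k = 0.25  # cycles/mm, narrow enough that truncation is negligible
        kx, ky = SPEC.k_axes()
        filt = np.exp(-0.5 * (kx[None, :] ** 2 + ky[:, None] ** 2) / sigma_k**2)
        expected = 2 * math.sqrt(2 * math.log(2)) / (2 * math.pi * sigma_k)
        measured = measure_psf_fwhm(filt, SPEC)
        assert measured == pytest.approx(expected, rel=0.01)

    def test_identity_filter_gives_sinc_mainlobe(self):
        # brute-force oracle: FWHM of |sinc| from the rect truncation window,
        # approximately 1.21 pixels
        filt = np.ones((SPEC.matrix, SPEC.matrix))
        measured = measure_psf_fwhm(filt, SPEC, pad_factor=16)
        n = SPEC.matrix
        x = np.linspace(-2, 2, 20001)  # pixels
        profile = np.abs(np.sin(np.pi * x)) / np.maximum(
            np.abs(np.sin(np.pi * x / n)), 1e-300
        )
        profile[x == 0] = n
        half = profile.max() / 2
        above = profile >= half
        width_px = x[above].max() - x[above].min()
        assert measured / SPEC.pixel_mm == pytest.approx(width_px, rel=0.02)
        assert measured / SPEC.pixel_mm == pytest.approx(1.21, abs=0.02)

    def test_monotone_in_sigma(self):
        kx, ky = SPEC.k_axes()
        k2 = kx[None, :] ** 2 + ky[:, None] ** 2
        f1 = measure_psf_fwhm(np.exp(-0.5 * k2 / 0.1**2), SPEC)
        f2 = measure_psf_fwhm(np.exp(-0.5 * k2 / 0.2**2), SPEC)
        assert f1 > f2

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            measure_psf_fwhm(np.ones((64, 64)), SPEC)


class TestCalibrateFilter:
    def test_native_is_identity(self):
        d = calibrate_filter(0.7, SPEC)
        assert d.is_identity
        img = np.random.default_rng(0).normal(size=(128, 128)) + 0j
        out = apply_lowpass(img, d)
        np.testing.assert_array_equal(out, img)

    def test_sharpening_raises(self):
        with pytest.raises(ValueError):
            calibrate_filter(0.5, SPEC)

    @pytest.mark.parametrize("target", PAPER_RESOLUTIONS_MM)
    def test_all_paper_resolutions_within_one_percent(self, target):
        d = calibrate_filter(target, SPEC)
        if d.is_identity:
            assert target == SPEC.native_dx_mm
        else:
            assert abs(d.measured_fwhm_mm - target) / target <= 0.01
            # independent re-measurement of the exported filter
            remeasured = measure_psf_fwhm(d.kspace_filter(), SPEC)
            assert abs(remeasured - target) / target <= 0.01

    def test_unit_dc_gain(self):
        d = calibrate_filter(1.3, SPEC)
        filt = d.kspace_filter()
        assert filt[SPEC.matrix // 2, SPEC.matrix // 2] == pytest.approx(1.0)
        assert filt.max() <= 1.0

    def test_json_round_trip(self):
        d = calibrate_filter(1.2, SPEC)
        d2 = FilterDesign.from_json(d.to_json())
        assert d2 == d


class TestApplyLowpass:
    def test_constant_image_unchanged(self):
        d = calibrate_filter(1.7, SPEC)
        img = np.full((128, 128), 3.0 + 1.0j)
        out = apply_lowpass(img, d)
        np.testing.assert_allclose(out, img, atol=1e-10)

    def test_linearity(self, rng):
        d = calibrate_filter(1.2, SPEC)
        x = rng.normal(size=(128, 128)) + 1j * rng.normal(size=(128, 128))
        y = rng.normal(size=(128, 128)) + 1j * rng.normal(size=(128, 128))
        lhs = apply_lowpass(2.0 * x + 0.5 * y, d)
        rhs = 2.0 * apply_lowpass(x, d) + 0.5 * apply_lowpass(y, d)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_energy_non_increase(self, rng):
        for target in (0.9, 1.2, 1.7):
            d = calibrate_filter(target, SPEC)
            x = rng.normal(size=(128, 128)) + 1j * rng.normal(size=(128, 128))
            assert np.linalg.norm(apply_lowpass(x, d)) <= np.linalg.norm(x) + 1e-9

    def test_shape_mismatch_raises(self):
        d = calibrate_filter(1.2, SPEC)
        with pytest.raises(ValueError):
            apply_lowpass(np.zeros((64, 64), complex), d)

    def test_non_finite_raises(self):
        d = calibrate_filter(1.2, SPEC)
        img = np.zeros((128, 128), complex)
        img[0, 0] = np.nan
        with pytest.raises(ValueError):
            apply_lowpass(img, d)

    def test_matches_spatial_convolution_oracle_16(self, rng):
        # small instance so the quadruple loop stays fast
        spec = ResolutionSpec(matrix=16, fov_mm=16 * 0.7)
        kx, ky = spec.k_axes()
        k2 = kx[None, :] ** 2 + ky[:, None] ** 2
        sigma_k = 0.3
        filt = np.exp(-0.5 * k2 / sigma_k**2)
        d = FilterDesign(
            sigma_k=sigma_k,
            target_dx_mm=float("nan"),
            measured_fwhm_mm=float("nan"),
            is_identity=False,
            matrix=16,
            fov_mm=spec.fov_mm,
        )
        img = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        fast = apply_lowpass(img, d)
        slow = brute_force_circular_convolution(img, filt)
        np.testing.assert_allclose(fast, slow, rtol=1e-10, atol=1e-12)


class TestDegradeSlice:
    def test_native_identity_with_metadata(self, noise_free_cohort):
        s = noise_free_cohort.slices[0]
        out = psf.degrade_slice(s, 0.7)
        np.testing.assert_array_equal(out.image, s.image)
        assert out.effective_dx_mm == 0.7

    def test_masks_untouched_and_edges_widen(self, noise_free_cohort):
        s = next(x for x in noise_free_cohort.slices if x.gt_scar.sum() > 60)
        out = psf.degrade_slice(s, 1.7)
        np.testing.assert_array_equal(out.gt_scar, s.gt_scar)
        np.testing.assert_array_equal(out.gt_myo, s.gt_myo)
        np.testing.assert_array_equal(out.remote_roi, s.remote_roi)
        # 10-90% edge width across the scar boundary grows under blurring
        row = np.argmax(s.gt_scar.sum(axis=1))
        before = np.abs(s.image[row])
        after = np.abs(out.image[row])

        def edge_width(profile):
            p = (profile - profile.min()) / (profile.max() - profile.min())
            return np.sum((p > 0.1) & (p < 0.9))

        assert edge_width(after) >= edge_width(before)

    def test_sweep_shapes_constant(self, noise_free_cohort):
        s = noise_free_cohort.slices[0]
        for dx in PAPER_RESOLUTIONS_MM:
            out = psf.degrade_slice(s, dx)
            assert out.image.shape == (128, 128)
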