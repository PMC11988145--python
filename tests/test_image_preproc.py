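"""Normalisation, standardisation and wavelet hard-threshold denoising."""

import numpy as np
import pytest

from apocvit.image_preproc import (DenoiseConfig, denoise_image, dwt2,
                                   hard_threshold, idwt2, normalize_image,
                                   preprocess_image, standardize_image,
                                   universal_threshold)


class TestNormalize:
    def test_affine_map_example(self):
        out = normalize_image(np.array([[0.0, 5.0], [10.0, 5.0]]))
        assert np.allclose(out, [[0.0, 0.5], [1.0, 0.5]])

    def test_range_is_unit_interval(self, rng):
        out = normalize_image(rng.normal(10, 3, (17, 23)))
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_image_warns_and_returns_zeros(self):
        with pytest.warns(RuntimeWarning, match="constant image"):
            out = normalize_image(np.full((2, 2), 7.0))
        assert np.all(out == 0.0)


class TestStandardize:
    def test_two_point_zscore(self):
        assert np.allclose(standardize_image(np.array([[1.0, 3.0]])), [[-1, 1]])

    def test_mean_zero_std_one(self, rng):
        out = standardize_image(rng.normal(4, 2, (31, 12)))
        assert abs(out.mean()) < 1e-9
        assert abs(out.std() - 1.0) < 1e-9

    def test_idempotent(self, rng):
        x = rng.normal(0, 5, (16, 16))
        once = standardize_image(x)
        assert np.allclose(standardize_image(once), once, atol=1e-9)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            standardize_image(np.ones((3, 3)))


class TestWavelet:
    def test_haar_constant_2x2(self):
        # orthonormal Haar on a constant 2x2 block: approximation 2c, no detail
        c = 3.25
        dec = dwt2(np.full((2, 2), c), "haar", 1)
        assert np.allclose(dec.coefficients[0], 2 * c)
        for band in dec.coefficients[1]:
            assert np.allclose(band, 0.0)

    @pytest.mark.parametrize("wavelet,level", [("db4", 2), ("haar", 3),
                                               ("sym4", 1)])
    def test_parseval_energy(self, rng, wavelet, level):
        img = rng.normal(0, 1, (64, 64))
        dec = dwt2(img, wavelet, level)
        assert np.isclose(dec.total_energy(), np.sum(img ** 2), rtol=1e-6)

    @pytest.mark.parametrize("shape", [(32, 32), (48, 40), (64, 96)])
    def test_round_trip_identity(self, rng, shape):
        img = rng.normal(0, 1, shape)
        assert np.max(np.abs(idwt2(dwt2(img)) - img)) < 1e-8

    def test_too_many_levels_raises(self):
        with pytest.raises(ValueError, match="levels"):
            dwt2(np.zeros((8, 8)), "db4", 5)

    def test_unknown_wavelet_raises(self):
        with pytest.raises(ValueError):
            dwt2(np.zeros((32, 32)), "nosuchwavelet", 1)


class TestHardThreshold:
    def test_kills_small_keeps_large(self):
        dec = dwt2(np.arange(64.0).reshape(8, 8), "haar", 1)
        details = np.array([3.2, -0.5, 1.1, -4.0])
        dec.coefficients[1] = (details.copy(), details.copy(), details.copy())
        out = hard_threshold(dec, 1.0)
        for band in out.coefficients[1]:
            assert np.allclose(band, [3.2, 0.0, 1.1, -4.0])

    def test_lambda_zero_is_identity(self, rng):
        dec = dwt2(rng.normal(0, 1, (32, 32)), "db4", 2)
        out = hard_threshold(dec, 0.0)
        for a, b in zip(out.coefficients[1:], dec.coefficients[1:]):
            for x, y in zip(a, b):
                assert np.array_equal(x, y)

    def test_idempotent(self, rng):
        dec = dwt2(rng.normal(0, 1, (32, 32)), "db4", 2)
        once = hard_threshold(dec, 0.7)
        twice = hard_threshold(once, 0.7)
        for a, b in zip(once.coefficients[1:], twice.coefficients[1:]):
            for x, y in zip(a, b):
                assert np.array_equal(x, y)

    def test_never_increases_energy(self, rng):
        dec = dwt2(rng.normal(0, 1, (32, 32)), "db4", 2)
        assert hard_threshold(dec, 0.5).total_energy() <= dec.total_energy()

    def test_approximation_band_untouched(self, rng):
        dec = dwt2(rng.normal(0, 1, (16, 16)), "haar", 2)
        out = hard_threshold(dec, 1e9)
        assert np.array_equal(out.coefficients[0], dec.coefficients[0])

    def test_negative_lambda_rejected(self, rng):
        dec = dwt2(rng.normal(0, 1, (8, 8)), "haar", 1)
        with pytest.raises(ValueError):
            hard_threshold(dec, -1.0)


class TestDenoise:
    def test_fixed_lambda_zero_is_identity(self, rng):
        img = rng.normal(0, 1, (32, 32))
        cfg = DenoiseConfig(threshold_mode="fixed", lam=0.0)
        assert np.max(np.abs(denoise_image(img, cfg) - img)) < 1e-8

    def test_removed_energy_matches_removed_details(self, rng):
        # thresholding every detail leaves the approximation-only image;
        # the removed energy equals the summed squared detail coefficients
        img = rng.normal(0, 1, (32, 32))
        dec = dwt2(img, "db4", 2)
        lam = max(np.abs(b).max() for lvl in dec.coefficients[1:]
                  for b in lvl) + 1.0
        smooth = idwt2(hard_threshold(dec, lam))
        residual = np.sum((img - smooth) ** 2)
        assert np.isclose(residual, dec.detail_energy(), rtol=1e-6)

    def test_universal_mode_reduces_hair_artifact_mse(self):
        # Monte-Carlo over generator-style hair speckle on a smooth scene
        improved = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            yy, xx = np.mgrid[0:64, 0:64]
            clean = 0.4 + 0.3 * np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / 200)
            noisy = clean + rng.normal(0, 0.04, clean.shape)
            for _ in range(40):   # short high-amplitude streaks
                y0, x0 = rng.integers(0, 60, 2)
                noisy[y0:y0 + 4, x0] += rng.normal(0, 0.15)
            den = denoise_image(noisy, DenoiseConfig())
            if np.mean((den - clean) ** 2) < np.mean((noisy - clean) ** 2):
                improved += 1
        assert improved >= 18

    def test_warm_region_peak_location_preserved(self, small_raw):
        spec, raw = small_raw
        estrus = [(im, lat) for im, lat in zip(raw["images"], raw["latents"])
                  if lat["label"] == 1 and not lat["occluded"]]
        from scipy.ndimage import gaussian_filter
        for img, lat in estrus[:6]:
            den = denoise_image(img, DenoiseConfig())
            # the warm-region maximum: argmax of the lightly smoothed field
            peak = np.unravel_index(np.argmax(gaussian_filter(den, 2.0)),
                                    den.shape)
            cy, cx = lat["center"]
            assert np.hypot(peak[0] - cy, peak[1] - cx) <= 3.0

    def test_pipeline_deterministic(self, rng):
        img = rng.normal(0, 1, (32, 32)) + 5
        a = preprocess_image(img)
        b = preprocess_image(img)
        assert np.array_equal(a, b)

    def test_universal_threshold_formula(self, rng):
        img = rng.normal(0, 1, (32, 32))
        dec = dwt2(img, "db4", 2)
        lam = universal_threshold(dec, img.size)
        sigma = np.median(np.abs(dec.coefficients[-1][2])) / 0.6745
        assert np.isclose(lam, sigma * np.sqrt(2 * np.log(img.size)))
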