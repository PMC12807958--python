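"""Image-quality metrics: SNR, segmentation, FWHM recovery, SSIM properties."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from csmprage.qc import (brain_mask, abs_difference, segment_tissues_basic,
                         smoothness_fwhm, ssim3d, tissue_snr)


def _fwhm_to_sigma(fwhm):
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class TestTissueSNR:
    def test_matches_analytic_mean_over_sd(self):
        rng = np.random.default_rng(0)
        img = 50.0 + rng.normal(scale=5.0, size=(22, 22, 22))
        mask = np.zeros(img.shape, bool)
        mask.ravel()[:10000] = True
        vals = img[mask]
        oracle = vals.mean() / vals.std(ddof=1)
        est = tissue_snr(img, mask)
        assert est == pytest.approx(oracle, abs=1e-12)
        assert est == pytest.approx(10.0, abs=0.3)

    def test_constant_image_gives_sentinel(self):
        img = np.full((8, 8, 8), 3.0)
        assert np.isinf(tissue_snr(img, np.ones(img.shape, bool)))

    def test_tiny_mask_rejected(self):
        img = np.zeros((8, 8, 8))
        mask = np.zeros((8, 8, 8), bool)
        mask[0, 0, 0] = True
        with pytest.raises(ValueError):
            tissue_snr(img, mask)


class TestSegmentation:
    def test_three_delta_histogram_recovered_exactly(self):
        rng = np.random.default_rng(1)
        img = np.zeros((24, 24, 24))
        labs = rng.integers(0, 3, size=img.shape)
        img[labs == 0] = 0.15
        img[labs == 1] = 0.65
        img[labs == 2] = 1.0
        gm, wm, csf = segment_tissues_basic(img, np.ones(img.shape, bool))
        assert np.array_equal(csf, labs == 0)
        assert np.array_equal(gm, labs == 1)
        assert np.array_equal(wm, labs == 2)

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        img = rng.random((16, 16, 16))
        a = segment_tissues_basic(img, np.ones(img.shape, bool))
        b = segment_tissues_basic(img, np.ones(img.shape, bool))
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_wm_dice_on_noise_free_phantom(self, phantom64):
        from csmprage.phantom import LABEL_WM

        img = phantom64.intensity_volume
        gm, wm, csf = segment_tissues_basic(img, phantom64.brain_mask())
        truth = phantom64.tissue_mask(LABEL_WM)
        dice = 2 * np.logical_and(wm, truth).sum() / (wm.sum() + truth.sum())
        assert dice >= 0.95

    def test_degenerate_intensities_rejected(self):
        img = np.ones((16, 16, 16))
        with pytest.raises(ValueError):
            segment_tissues_basic(img, np.ones(img.shape, bool))


class TestFWHM:
    @pytest.mark.parametrize("kernel_fwhm", [2.0, 3.0, 4.0, 6.0])
    def test_recovers_applied_kernel(self, kernel_fwhm):
        sigma = _fwhm_to_sigma(kernel_fwhm)
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            img = gaussian_filter(rng.normal(size=(64, 64, 64)), sigma, mode="wrap")
            *_, comb, _ = smoothness_fwhm(img, np.ones(img.shape, bool))
            errs.append(comb / kernel_fwhm - 1.0)
        assert abs(np.mean(errs)) < 0.15

    def test_white_noise_near_zero_width(self):
        # i.i.d. noise has no spatial correlation: the estimate collapses
        # toward zero or the sentinel, never to a sizable width
        for seed in range(10):
            rng = np.random.default_rng(seed)
            img = rng.normal(size=(64, 64, 64))
            *_, comb, _ = smoothness_fwhm(img, np.ones(img.shape, bool))
            assert np.isnan(comb) or comb < 1.2

    def test_monotone_in_smoothing(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(48, 48, 48))
        a = gaussian_filter(base, 1.0, mode="wrap")
        b = gaussian_filter(base, 2.0, mode="wrap")
        mask = np.ones(base.shape, bool)
        assert smoothness_fwhm(b, mask)[3] > smoothness_fwhm(a, mask)[3]

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            smoothness_fwhm(np.ones((16, 16, 16)), np.ones((16, 16, 16), bool))


class TestSSIM:
    def test_self_similarity_is_one(self, phantom64):
        x = phantom64.intensity_volume
        assert ssim3d(x, x).mean_ssim == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self, phantom64):
        rng = np.random.default_rng(4)
        a = phantom64.intensity_volume
        b = a + 0.05 * rng.normal(size=a.shape)
        assert ssim3d(a, b).mean_ssim == pytest.approx(ssim3d(b, a).mean_ssim,
                                                       abs=1e-12)

    def test_inverted_contrast_scores_low(self, phantom64):
        a = phantom64.intensity_volume
        b = a.max() - a
        assert ssim3d(a, b).mean_ssim < 0.5

    def test_monotone_decrease_with_noise(self, phantom64):
        a = phantom64.intensity_volume
        vals = []
        for sd in (0.01, 0.05, 0.1):
            scores = []
            for seed in range(5):
                rng = np.random.default_rng(seed)
                scores.append(ssim3d(a, a + rng.normal(scale=sd, size=a.shape)).mean_ssim)
            vals.append(np.mean(scores))
        assert vals[0] > vals[1] > vals[2]

    def test_matches_skimage_reference(self, phantom64):
        """Cross-check against an independent SSIM implementation.

        The reference crops a window-radius border before averaging, so the
        comparison restricts both maps to the same interior region.
        """
        from skimage.metrics import structural_similarity

        rng = np.random.default_rng(5)
        a = phantom64.intensity_volume
        b = a + 0.05 * rng.normal(size=a.shape)
        interior = np.zeros(a.shape, bool)
        interior[6:-6, 6:-6, 6:-6] = True
        ours = ssim3d(a, b, mask=interior).mean_ssim
        _, ref_map = structural_similarity(
            a, b, gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
            data_range=float(max(a.max(), b.max())), full=True)
        assert ours == pytest.approx(float(ref_map[interior].mean()), abs=5e-3)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssim3d(np.zeros((8, 8, 8)), np.zeros((8, 8, 9)))


class TestAbsDifference:
    def test_identical_is_zero_and_symmetric(self):
        rng = np.random.default_rng(6)
        a = rng.random((12, 12, 12))
        b = rng.random((12, 12, 12))
        assert np.all(abs_difference(a, a) == 0)
        assert np.array_equal(abs_difference(a, b), abs_difference(b, a))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            abs_difference(np.zeros((4, 4, 4)), np.zeros((5, 4, 4)))


def test_brain_mask_covers_brain(phantom64):
    m = brain_mask(phantom64.intensity_volume)
    truth = phantom64.brain_mask()
    overlap = np.logical_and(m, truth).sum() / truth.sum()
    assert overlap > 0.98
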