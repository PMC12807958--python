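"""Morphometry proxy and agreement statistics."""

import numpy as np
import pandas as pd
import pytest

from csmprage.morphometry import (between_sequence_r2, estimate_thickness,
                                  estimate_volumes, read_aseg_stats,
                                  repeatability)
from csmprage.phantom import (AcquisitionParams, apply_sampling_mask,
                              make_coils, make_phantom, simulate_kspace)
from csmprage.recon import cs_recon, zero_filled_recon
from csmprage.sampling import full_mask, phyllotaxis_mask


@pytest.fixture(scope="module")
def clean_image64(phantom64, coils64):
    """Noise-free fully sampled reconstruction (no bias field)."""
    params = AcquisitionParams(matrix=phantom64.shape, noise_sd=0.0,
                               turbo_factor=64, seed=0)
    ks = apply_sampling_mask(simulate_kspace(phantom64, coils64, None, params),
                             full_mask(64, 64))
    return zero_filled_recon(ks, coils64).volume


class TestVolumes:
    def test_noise_free_raw_growing_recovers_closely(self, phantom64, clean_image64):
        """Without pre-smoothing the grown region tracks the labeled ellipsoid.

        Texture-dark WM voxels bordering a structure can fall inside its
        intensity band; on the small test-phantom structures this adds up
        to a few percent of leakage.
        """
        t = estimate_volumes(clean_image64, phantom64.structures,
                             presmooth_sigma=0.0)
        rel = t.estimate.values / phantom64.structures.vol_mm3.values - 1.0
        assert np.all(np.abs(rel) <= 0.07)

    def test_noise_free_default_estimator_small_bias(self, phantom64, clean_image64):
        # the default light pre-smooth erodes curved boundaries slightly;
        # on these small test structures the bias stays under 8%
        t = estimate_volumes(clean_image64, phantom64.structures)
        rel = t.estimate.values / phantom64.structures.vol_mm3.values - 1.0
        assert np.all(np.abs(rel) <= 0.08)

    def test_identical_images_identical_tables(self, phantom64, clean_image64):
        a = estimate_volumes(clean_image64, phantom64.structures)
        b = estimate_volumes(clean_image64, phantom64.structures)
        pd.testing.assert_frame_equal(a, b)

    def test_contrast_erased_gives_missing_sentinel(self, phantom64, coils64):
        """Heavy over-regularization washes out subcortical contrast."""
        params = AcquisitionParams(matrix=phantom64.shape, noise_sd=0.0,
                                   turbo_factor=64, seed=0)
        m8 = phyllotaxis_mask(64, 64, 8, turbo=64, seed=6)
        ks = apply_sampling_mask(
            simulate_kspace(phantom64, coils64, None, params), m8)
        blown = cs_recon(ks, m8, coils64, lam=0.1, max_iter=30, tol=0.0,
                         dtype=np.complex64)
        t = estimate_volumes(blown.volume, phantom64.structures)
        # at least the lowest-contrast structure is gone or unrecognizable
        worst = t.estimate.iloc[-1]  # structures ordered by rising intensity
        truth = phantom64.structures.vol_mm3.iloc[-1]
        assert np.isnan(worst) or abs(worst / truth - 1.0) > 0.5


class TestThickness:
    def test_uniform_ribbon_recovered(self, coils64):
        p = make_phantom((64, 64, 64), 0, seed=2, thickness_mm=4.0)
        params = AcquisitionParams(matrix=p.shape, noise_sd=0.0,
                                   turbo_factor=64, seed=0)
        ks = apply_sampling_mask(simulate_kspace(p, coils64, None, params),
                                 full_mask(64, 64))
        img = zero_filled_recon(ks, coils64).volume
        t = estimate_thickness(img, p)
        assert np.all(np.abs(t.estimate.values - 4.0) <= 0.5)

    def test_thicker_ribbon_gives_larger_estimates(self, coils64):
        ests = []
        for thickness in (4.0, 6.0):
            p = make_phantom((64, 64, 64), 0, seed=2, thickness_mm=thickness)
            params = AcquisitionParams(matrix=p.shape, noise_sd=0.0,
                                       turbo_factor=64, seed=0)
            ks = apply_sampling_mask(simulate_kspace(p, coils64, None, params),
                                     full_mask(64, 64))
            img = zero_filled_recon(ks, coils64).volume
            ests.append(estimate_thickness(img, p).estimate.values)
        assert np.all(ests[1] > ests[0])

    def test_identical_images_identical_estimates(self, phantom64, clean_image64):
        a = estimate_thickness(clean_image64, phantom64)
        b = estimate_thickness(clean_image64, phantom64)
        pd.testing.assert_frame_equal(a, b)


def _table(values, kind="volume"):
    return pd.DataFrame({"id": [f"s{i}" for i in range(len(values))],
                         "kind": kind, "estimate": values})


class TestRepeatability:
    def test_identical_is_hundred_percent(self):
        t = _table([10.0, 20.0, 30.0])
        assert np.allclose(repeatability(t, t).repeatability_pct, 100.0)

    def test_hand_computed_value(self):
        r = repeatability(_table([100.0]), _table([90.0]))
        assert r.repeatability_pct.iloc[0] == pytest.approx(100 * (1 - 10 / 95))

    def test_symmetric_and_scale_invariant(self):
        a, b = _table([100.0, 50.0]), _table([90.0, 55.0])
        r1 = repeatability(a, b).repeatability_pct.values
        r2 = repeatability(b, a).repeatability_pct.values
        assert np.allclose(r1, r2)
        a10 = _table([1000.0, 500.0])
        b10 = _table([900.0, 550.0])
        assert np.allclose(repeatability(a10, b10).repeatability_pct, r1)

    def test_mismatched_structures_rejected(self):
        a = _table([1.0, 2.0])
        b = _table([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            repeatability(a, b)


class TestBetweenSequenceR2:
    def test_identical_gives_one(self):
        t = _table([1.0, 2.0, 3.0, 4.0])
        assert between_sequence_r2(t, t).r2.iloc[0] == pytest.approx(1.0)

    def test_affine_relation_gives_one(self):
        ref = _table([1.0, 2.0, 3.0, 4.0])
        cs = _table([2 * v + 5 for v in (1.0, 2.0, 3.0, 4.0)])
        assert between_sequence_r2(ref, cs).r2.iloc[0] == pytest.approx(1.0)

    def test_hand_computed_four_point_example(self):
        ref = _table([1.0, 2.0, 3.0, 4.0])
        cs = _table([1.1, 1.9, 3.2, 3.8])
        r2 = between_sequence_r2(ref, cs).r2.iloc[0]
        oracle = np.corrcoef([1, 2, 3, 4], [1.1, 1.9, 3.2, 3.8])[0, 1] ** 2
        assert r2 == pytest.approx(oracle, abs=1e-12)
        assert r2 == pytest.approx(0.98178, abs=1e-4)

    def test_zero_variance_gives_nan(self):
        ref = _table([1.0, 1.0, 1.0])
        cs = _table([1.0, 2.0, 3.0])
        assert np.isnan(between_sequence_r2(ref, cs).r2.iloc[0])

    def test_too_few_structures_rejected(self):
        with pytest.raises(ValueError):
            between_sequence_r2(_table([1.0, 2.0]), _table([1.0, 2.0]))


def test_read_aseg_stats_roundtrip(tmp_path):
    text = """# Title Segmentation Statistics
# ColHeaders Index SegId NVoxels Volume_mm3 StructName normMean
 1  10  7583  7583.0  Left-Thalamus  88.1
 2  11  3871  3871.0  Left-Caudate  80.2
 3  17  4213  4213.0  Left-Hippocampus  71.5
"""
    f = tmp_path / "aseg.stats"
    f.write_text(text)
    t = read_aseg_stats(f)
    assert list(t.id) == ["Left-Thalamus", "Left-Caudate", "Left-Hippocampus"]
    assert t.estimate.tolist() == [7583.0, 3871.0, 4213.0]
    # parsed tables feed straight into the agreement operations
    assert between_sequence_r2(t, t).r2.iloc[0] == pytest.approx(1.0)
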