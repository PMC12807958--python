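"""Reconstruction: exactness, prox, oracle equivalence, convergence, limits."""

import numpy as np
import pytest

from csmprage.phantom import (AcquisitionParams, CoilSet, KSpaceData,
                              apply_sampling_mask, make_coils, make_phantom,
                              simulate_kspace)
from csmprage.recon import (ReconProblem, cs_recon, estimate_lipschitz,
                            objective, retro_reconstruct, soft_threshold,
                            wavelet_forward, wavelet_inverse,
                            zero_filled_recon)
from csmprage.recon import _coeff_l1, _forward, _threshold_coeffs
from csmprage.sampling import full_mask, phyllotaxis_mask


class TestSoftThreshold:
    def test_real_values(self):
        assert soft_threshold(np.array(3.0), 1.0) == pytest.approx(2.0)
        assert soft_threshold(np.array(-0.5), 1.0) == pytest.approx(0.0)

    def test_complex_magnitude_shrinkage_preserves_phase(self):
        w = 4.0 * np.exp(1j * np.pi / 3)
        out = soft_threshold(np.array(w), 1.0)
        assert out == pytest.approx(3.0 * np.exp(1j * np.pi / 3))

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.ones(3), -0.1)


def test_wavelet_orthogonal_round_trip():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(3, 64, 64)) + 1j * rng.normal(size=(3, 64, 64))
    back = wavelet_inverse(wavelet_forward(x))
    assert np.abs(back - x).max() < 1e-10


class TestObjective:
    def _problem(self, lam=0.1, n=16):
        rng = np.random.default_rng(1)
        mask = rng.random((n, n)) < 0.5
        sens = np.ones((1, 1, n, n), complex)
        y = np.zeros((1, 1, n, n), complex)
        return ReconProblem(y=y, mask=mask, sens=sens, lam=lam)

    def test_zero_everywhere_is_zero(self):
        p = self._problem()
        assert objective(np.zeros((1, 16, 16), complex), p) == 0.0

    def test_data_term_half_norm_squared(self):
        p = self._problem(lam=0.5)
        p.y = p.y.copy()
        p.y[0, 0, 0, 0] = np.sqrt(2)  # ||y||^2 = 2
        p.mask = np.zeros((16, 16), bool)  # A x = 0 regardless of x
        assert objective(np.zeros((1, 16, 16), complex), p) == pytest.approx(1.0)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            self._problem(lam=-1e-4)


def test_lambda0_full_sampling_matches_direct_inverse(clean_kspace64, coils64):
    m = full_mask(64, 64)
    ksm = apply_sampling_mask(clean_kspace64, m)
    zf = zero_filled_recon(ksm, coils64)
    cs = cs_recon(ksm, m, coils64, lam=0.0)
    err = np.abs(cs.volume - zf.volume).max() / zf.volume.max()
    assert err < 1e-6


def test_zero_filled_exact_for_uniform_coil(phantom64, bias64):
    flat = make_coils(phantom64.shape, 1, flat=True, normalize=False)
    params = AcquisitionParams(matrix=phantom64.shape, noise_sd=0.0, turbo_factor=64)
    ks = simulate_kspace(phantom64, flat, None, params)
    zf = zero_filled_recon(ks, flat)
    err = np.abs(zf.volume - phantom64.intensity_volume).max()
    assert err / phantom64.intensity_volume.max() < 1e-10
    assert np.all(zf.volume >= 0)


def test_undersampled_zero_filled_worse_than_full(clean_kspace64, coils64, phantom64, bias64):
    truth = phantom64.intensity_volume * bias64.field
    bm = phantom64.brain_mask()

    def rmse(vol):
        return np.sqrt(np.mean((vol - truth)[bm] ** 2))

    zf_full = zero_filled_recon(
        apply_sampling_mask(clean_kspace64, full_mask(64, 64)), coils64)
    m4 = phyllotaxis_mask(64, 64, 4, turbo=64, seed=5)
    zf4 = zero_filled_recon(apply_sampling_mask(clean_kspace64, m4), coils64)
    assert rmse(zf4.volume) > rmse(zf_full.volume)


def test_cs_improves_on_zero_filled_noise_free(clean_kspace64, coils64, phantom64, bias64):
    """With the l1 prior inpainting missing k-space, CS beats zero-filling."""
    truth = phantom64.intensity_volume * bias64.field
    bm = phantom64.brain_mask()
    m4 = phyllotaxis_mask(64, 64, 4, turbo=64, seed=5)
    ksm = apply_sampling_mask(clean_kspace64, m4)
    zf = zero_filled_recon(ksm, coils64)
    cs = cs_recon(ksm, m4, coils64, lam=0.0003, tol=0.0, dtype=np.complex64)
    rmse_zf = np.sqrt(np.mean((zf.volume - truth)[bm] ** 2))
    rmse_cs = np.sqrt(np.mean((cs.volume - truth)[bm] ** 2))
    assert rmse_cs < rmse_zf


def test_objective_decreases_start_to_end(noisy_kspace64, coils64):
    m4 = phyllotaxis_mask(64, 64, 4, turbo=64, seed=5)
    ksm = apply_sampling_mask(noisy_kspace64, m4)
    cs = cs_recon(ksm, m4, coils64, lam=0.0003, max_iter=20, tol=0.0,
                  dtype=np.complex64)
    trace = [f for _, f in cs.objective_trace]
    assert trace[-1] < trace[0]


def _toy_kspace(seed, n=16, noise=0.02):
    """Single-coil 16x16 toy acquisition (one readout position)."""
    rng = np.random.default_rng(seed)
    img = np.zeros((n, n))
    img[4:12, 4:12] = 1.0
    img[6:10, 6:10] = 0.5
    img = img + 0.05 * rng.normal(size=(n, n))
    mask = rng.random((n, n)) < 0.5
    mask[n // 2 - 2:n // 2 + 3, n // 2 - 2:n // 2 + 3] = True

    k = np.fft.fftshift(np.fft.fft2(img))  # unnormalized forward DFT
    k = k + noise * np.sqrt(n * n) * (rng.normal(size=(n, n))
                                      + 1j * rng.normal(size=(n, n)))
    k = k * mask
    # embed the 2D problem in a 16^3 acquisition whose energy sits entirely
    # in readout slice 0 (constant along the readout frequency axis)
    k3 = np.broadcast_to(k, (n, n, n)).copy()
    params = AcquisitionParams(matrix=(n, n, n), turbo_factor=n)
    ks = KSpaceData(data=k3[None], params=params, noise_seed=seed)
    coils = CoilSet(sensitivities=np.ones((1, n, n, n), complex), n_coils=1,
                    centers=np.zeros((1, 3)), width=0.0)

    class _Mask:
        pass

    _Mask.mask = mask
    _Mask.seed = seed
    return ks, _Mask, coils


def _ista(problem, n_iter=500):
    """Brute-force proximal-gradient reference at fixed step 1/L."""
    from csmprage.recon import _adjoint

    L = estimate_lipschitz(problem.sens, problem.mask, seed=123)
    x = _adjoint(problem.y, problem.sens, problem.mask)
    for _ in range(n_iter):
        g = _adjoint(_forward(x, problem.sens, problem.mask) - problem.y,
                     problem.sens, problem.mask)
        w = wavelet_forward(x - g / L)
        w = _threshold_coeffs(w, problem.lam / L)
        x = wavelet_inverse(w)
    return x


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_fista_matches_ista_oracle(seed):
    """FISTA attains the 500-iteration ISTA objective (to 1e-8 or better).

    Both solvers minimize the identical (normalized) slice problem; the
    accelerated scheme must never end above the plain proximal-gradient
    reference, and must stay in the same basin (gap bounded).
    """
    from csmprage.recon import _prepare_problem

    ks, mask, coils = _toy_kspace(seed)
    lam = 0.01
    problem, _, _ = _prepare_problem(ks, mask, coils, lam, np.complex128)
    x_ista = _ista(problem, 500)
    f_ista = objective(x_ista, problem)

    cs = cs_recon(ks, mask, coils, lam=lam, max_iter=500, tol=0.0)
    f_fista = cs.objective_trace[-1][1]
    assert f_fista <= f_ista + 1e-8
    assert abs(f_fista - f_ista) < 1e-4  # same minimum, ISTA tail not yet flat


def test_over_regularization_concentrates_energy_in_coarse_band(
        clean_kspace64, coils64):
    m4 = phyllotaxis_mask(64, 64, 4, turbo=64, seed=5)
    ksm = apply_sampling_mask(clean_kspace64, m4)
    cs = cs_recon(ksm, m4, coils64, lam=1e3, max_iter=30, tol=0.0,
                  dtype=np.complex64)
    coeffs = wavelet_forward(cs.volume.astype(complex))
    coarse = float(np.sum(np.abs(coeffs[0]) ** 2))
    detail = sum(float(np.sum(np.abs(a) ** 2)) for lvl in coeffs[1:] for a in lvl)
    assert detail < 1e-3 * max(coarse, 1e-30)


def test_retro_reconstruct_shares_kspace_and_is_deterministic(
        noisy_kspace64, coils64):
    m8 = phyllotaxis_mask(64, 64, 8, turbo=64, seed=6)
    ksm = apply_sampling_mask(noisy_kspace64, m8)
    lams = [0.0003, 0.0003, 0.0012]
    vols = retro_reconstruct(ksm, m8, coils64, lams, max_iter=10, tol=0.0,
                             dtype=np.complex64)
    assert len(vols) == 3
    assert np.array_equal(vols[0].volume, vols[1].volume)  # duplicate lam
    assert not np.array_equal(vols[0].volume, vols[2].volume)
    assert all(v.provenance["mask_seed"] == 6 for v in vols)


def test_retro_reconstruct_empty_list_rejected(noisy_kspace64, coils64):
    m = phyllotaxis_mask(64, 64, 4, turbo=64, seed=5)
    with pytest.raises(ValueError):
        retro_reconstruct(apply_sampling_mask(noisy_kspace64, m), m, coils64, [])
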