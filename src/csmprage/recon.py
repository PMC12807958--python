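"""Image reconstruction from (under-)sampled multi-coil k-space.

Two reconstructions are provided:

* ``zero_filled_recon`` — inverse 3D DFT per coil followed by a
  sensitivity-weighted coil combination; exact for fully sampled data and
  the unregularized baseline for under-sampled data.

* ``cs_recon`` — compressed-sensing reconstruction.  A 1D inverse DFT
  along the readout axis decouples the 3D problem into independent 2D
  problems per readout position; each solves

      min_x  1/2 sum_c || M o F (S_c o x) - y_c ||_2^2 + lambda ||Psi x||_1

  with M the sampling mask, S_c the coil sensitivities, F the *unitary*
  2D DFT and Psi an orthogonal Daubechies-4 wavelet transform (4 levels,
  periodic boundary).  The slice data are intensity-normalized to unit
  maximum before solving, so regularization factors on the order of
  1e-4..1e-3 — the scale used on scanner consoles — are meaningful.
  The solver is FISTA with a fixed 1/L step (L from power iteration on
  the normal operator) and magnitude soft-thresholding as the prox.

All slices are solved simultaneously as a batched array; the per-slice
structure is preserved because every operator acts only on the two
phase-encode axes.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
import scipy.fft as sfft

from .phantom import CoilSet, KSpaceData

__all__ = [
    "ReconProblem",
    "ReconVolume",
    "soft_threshold",
    "objective",
    "wavelet_forward",
    "wavelet_inverse",
    "estimate_lipschitz",
    "zero_filled_recon",
    "cs_recon",
    "retro_reconstruct",
]

WAVELET = "db4"
WAVELET_LEVELS = 4
_PE_AXES = (-2, -1)


@dataclass
class ReconProblem:
    """One (batched) 2D reconstruction problem after readout decoupling."""

    y: np.ndarray            # (n_coils, n_slices, n_ky, n_kz) masked unitary k-space
    mask: np.ndarray         # (n_ky, n_kz) bool
    sens: np.ndarray         # (n_coils, n_slices, n_ky, n_kz) complex
    lam: float
    wavelet: str = WAVELET
    levels: int = WAVELET_LEVELS

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("regularization factor must be >= 0")


@dataclass
class ReconVolume:
    """Reconstructed magnitude volume with solver provenance."""

    volume: np.ndarray
    lam: float
    iterations_run: int
    objective_trace: list[tuple[int, float]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.volume.shape


# ---------------------------------------------------------------------------
# Building blocks


def soft_threshold(w: np.ndarray, tau: float) -> np.ndarray:
    """Magnitude soft-thresholding: shrink |w| by tau, preserve phase/sign."""
    if tau < 0:
        raise ValueError("threshold must be >= 0")
    mag = np.abs(w)
    scale = np.maximum(mag - tau, 0.0) / np.where(mag > 0, mag, 1.0)
    return w * scale


def _usable_levels(n_ky: int, n_kz: int, levels: int) -> int:
    """Largest level count with even sizes throughout (exact periodized DWT)."""
    lv = 0
    while lv < levels and n_ky % 2 == 0 and n_kz % 2 == 0 and min(n_ky, n_kz) >= 2:
        n_ky //= 2
        n_kz //= 2
        lv += 1
    return max(lv, 1)


def wavelet_forward(x: np.ndarray, wavelet: str = WAVELET, levels: int = WAVELET_LEVELS):
    lv = _usable_levels(x.shape[-2], x.shape[-1], levels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return pywt.wavedec2(x, wavelet, mode="periodization", level=lv, axes=_PE_AXES)


def wavelet_inverse(coeffs, wavelet: str = WAVELET) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return pywt.waverec2(coeffs, wavelet, mode="periodization", axes=_PE_AXES)


def _coeff_l1(coeffs) -> float:
    total = float(np.sum(np.abs(coeffs[0])))
    for lvl in coeffs[1:]:
        for a in lvl:
            total += float(np.sum(np.abs(a)))
    return total


def _threshold_coeffs(coeffs, tau: float):
    out = [soft_threshold(coeffs[0], tau)]
    for lvl in coeffs[1:]:
        out.append(tuple(soft_threshold(a, tau) for a in lvl))
    return out


def _forward(x: np.ndarray, sens: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """A x = M o F(S_c o x) per coil (unitary 2D DFT, fft grid layout).

    The solver keeps y and the mask in the unshifted DFT layout (DC at
    index 0) so no per-iteration fftshift passes are needed; the cost is
    invariant under that index permutation.  Per-coil loops keep the
    working set cache-friendly.
    """
    out = np.empty(sens.shape, dtype=np.result_type(sens.dtype, x.dtype))
    for c in range(sens.shape[0]):
        k = sfft.fft2(sens[c] * x, axes=_PE_AXES, norm="ortho")
        np.multiply(k, mask, out=out[c])
    return out


def _gradient(resid: np.ndarray, sens: np.ndarray) -> np.ndarray:
    """sum_c conj(S_c) F^H resid_c for an already-masked residual."""
    g = None
    for c in range(sens.shape[0]):
        t = sfft.ifft2(resid[c], axes=_PE_AXES, norm="ortho")
        t *= np.conj(sens[c])
        g = t if g is None else g + t
    return g


def _adjoint(k: np.ndarray, sens: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return _gradient(k * mask, sens)


def objective(x: np.ndarray, problem: ReconProblem) -> float:
    """Cost 1/2 sum_c ||M F S_c x - y_c||^2 + lambda ||Psi x||_1."""
    resid = _forward(x, problem.sens, problem.mask) - problem.y
    data = 0.5 * float(np.sum(np.abs(resid) ** 2))
    if problem.lam == 0:
        return data
    return data + problem.lam * _coeff_l1(
        wavelet_forward(x, problem.wavelet, problem.levels))


def estimate_lipschitz(sens: np.ndarray, mask: np.ndarray, n_iter: int = 10,
                       seed: int = 0) -> float:
    """Power iteration on the normal operator A^H A; returns a step bound.

    For unit-RSS sensitivities the largest eigenvalue is <= 1 (M is a
    projection and F unitary); the estimate is inflated by 1% for safety.
    """
    rng = np.random.default_rng(seed)
    v = rng.normal(size=sens.shape[1:]) + 1j * rng.normal(size=sens.shape[1:])
    v = v.astype(sens.dtype)
    lam = 0.0
    for _ in range(n_iter):
        nv = float(np.linalg.norm(v.ravel()))
        if nv == 0:
            raise FloatingPointError("power iteration collapsed to zero vector")
        v /= nv
        v = _adjoint(_forward(v, sens, mask), sens, mask)
        lam = float(np.linalg.norm(v.ravel()))
    if not np.isfinite(lam) or lam <= 0:
        raise FloatingPointError("power iteration did not converge")
    return 1.01 * lam


# ---------------------------------------------------------------------------
# Reconstructions


def _combine(x_coils: np.ndarray, sens: np.ndarray | None) -> np.ndarray:
    if sens is None:
        return np.sqrt(np.sum(np.abs(x_coils) ** 2, axis=0))
    rss2 = np.sum(np.abs(sens) ** 2, axis=0)
    if float(rss2.min()) < 1e-12:
        raise ValueError("coil sensitivities vanish at some voxel; cannot combine")
    return np.sum(np.conj(sens) * x_coils, axis=0) / rss2


def zero_filled_recon(kspace: KSpaceData, coils: CoilSet | None) -> ReconVolume:
    """Direct inverse-DFT reconstruction with sensitivity-weighted combination.

    Exact for fully sampled noise-free data; for under-sampled data the
    missing columns stay zero and the result shows incoherent aliasing.
    """
    sens = coils.sensitivities if coils is not None else None
    if sens is not None and sens.shape != kspace.data.shape:
        raise ValueError("coil maps do not match k-space shape")
    x_coils = np.fft.ifftn(np.fft.ifftshift(kspace.data, axes=(2, 3)), axes=(1, 2, 3))
    combined = _combine(x_coils, sens)
    return ReconVolume(volume=np.abs(combined), lam=0.0, iterations_run=0,
                       objective_trace=[],
                       provenance={"method": "zero_filled",
                                   "noise_seed": kspace.noise_seed})


def _prepare_problem(kspace: KSpaceData, mask, coils: CoilSet, lam: float,
                     dtype) -> tuple[ReconProblem, np.ndarray, float]:
    m = np.asarray(mask.mask, dtype=bool)
    nc, nx, n_ky, n_kz = kspace.data.shape
    if m.shape != (n_ky, n_kz):
        raise ValueError("mask does not match k-space phase-encode grid")
    if coils.sensitivities.shape != kspace.data.shape:
        raise ValueError("coil maps do not match k-space shape")

    # readout decoupling, then unitary scaling of the per-slice 2D spectra;
    # stored in the unshifted DFT layout (DC at index 0) with the mask
    # permuted to match, so the iteration needs no fftshift passes
    y = sfft.ifft(kspace.data.astype(dtype), axis=1)
    y *= m[None, None] / np.sqrt(n_ky * n_kz)
    y = sfft.ifftshift(y, axes=_PE_AXES)
    m = sfft.ifftshift(m)
    sens = coils.sensitivities.astype(dtype)

    x0 = _gradient(y, sens)
    # Normalize the mean per-slice signal energy to one (the solver is a
    # stack of 2D slice problems).  On this scale console-style
    # regularization factors (1e-4..1e-3) weight the l1 term a few percent
    # of the cost: the default 3e-4 mildly denoises and 1.2e-3 visibly
    # smooths, the operating regime reported for scanner reconstructions.
    scale = float(np.linalg.norm(x0.ravel()) / np.sqrt(x0.shape[0]))
    if scale > 0:
        y = y / scale
        x0 = x0 / scale
    problem = ReconProblem(y=y, mask=m, sens=sens, lam=float(lam))
    return problem, x0, scale


def cs_recon(kspace: KSpaceData, mask, coils: CoilSet, lam: float,
             max_iter: int = 50, tol: float = 1e-6, *,
             dtype=np.complex128, lipschitz: float | None = None,
             power_seed: int = 0) -> ReconVolume:
    """Wavelet-regularized iterative reconstruction (FISTA, fixed 1/L step).

    The objective is evaluated at every iterate (the forward transform of
    the fresh iterate is cached and reused in the next gradient step, so
    the trace costs no extra FFTs) and the solver stops at ``max_iter`` or
    when the relative objective change drops below ``tol``.
    """
    if lam < 0:
        raise ValueError("regularization factor must be >= 0")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    problem, x0, scale = _prepare_problem(kspace, mask, coils, lam, dtype)
    return _solve(problem, x0, scale, max_iter, tol, lipschitz=lipschitz,
                  power_seed=power_seed,
                  provenance={"mask_seed": getattr(mask, "seed", None),
                              "noise_seed": kspace.noise_seed})


def _solve(problem: ReconProblem, x0: np.ndarray, scale: float,
           max_iter: int, tol: float, *, lipschitz: float | None = None,
           power_seed: int = 0, provenance: dict | None = None) -> ReconVolume:
    lam = problem.lam
    y, m, sens = problem.y, problem.mask, problem.sens

    if scale == 0.0:  # all-zero data: the minimizer is zero
        vol = np.zeros(x0.shape, dtype=float)
        return ReconVolume(vol, lam, 0, [(0, 0.0)], {"method": "cs", "L": 0.0})

    L = lipschitz if lipschitz is not None else estimate_lipschitz(sens, m, seed=power_seed)
    step = 1.0 / L
    tau = lam / L

    x = x0
    x_prev = x
    # cached residuals r = M F S x - y at the current and previous iterates;
    # the momentum point's residual is their linear combination, so each
    # iteration costs exactly one forward and one adjoint transform.
    r = _forward(x, sens, m) - y
    r_prev = r
    t = 1.0
    f = 0.5 * float(np.vdot(r, r).real)
    if lam > 0:
        f += lam * _coeff_l1(wavelet_forward(x))
    trace = [(0, f)]
    n_done = 0
    for it in range(1, max_iter + 1):
        beta = 0.0 if it == 1 else (t_prev - 1.0) / t
        z = x + beta * (x - x_prev)
        rz = r + beta * (r - r_prev)
        g = _gradient(rz, sens)
        w = wavelet_forward(z - step * g)
        w = _threshold_coeffs(w, tau) if tau > 0 else w
        x_new = wavelet_inverse(w)
        if x_new.dtype != x.dtype:
            x_new = x_new.astype(x.dtype)

        x_prev, x = x, x_new
        r_prev, r = r, _forward(x, sens, m) - y
        t_prev, t = t, 0.5 * (1.0 + float(np.sqrt(1.0 + 4.0 * t * t)))

        f_new = 0.5 * float(np.vdot(r, r).real)
        if lam > 0:
            f_new += lam * _coeff_l1(w)
        trace.append((it, f_new))
        n_done = it
        if tol > 0 and f > 0 and abs(f - f_new) <= tol * abs(f):
            f = f_new
            break
        f = f_new

    vol = np.abs(x).astype(float) * scale
    prov = {"method": "cs", "L": float(L), "max_iter": max_iter, "tol": tol}
    prov.update(provenance or {})
    return ReconVolume(volume=vol, lam=float(lam), iterations_run=n_done,
                       objective_trace=trace, provenance=prov)


def retro_reconstruct(kspace: KSpaceData, mask, coils: CoilSet,
                      lam_list, max_iter: int = 50, tol: float = 1e-6, *,
                      dtype=np.complex128) -> list[ReconVolume]:
    """Reconstruct the identical k-space at several regularization factors.

    Mirrors retrospective re-reconstruction on the scanner console: the
    acquired data are fixed and only lambda varies, so differences between
    the outputs are attributable to the regularization alone.  The
    Lipschitz bound is estimated once and shared.
    """
    lam_list = list(lam_list)
    if not lam_list:
        raise ValueError("lam_list must be non-empty")
    if any(l < 0 for l in lam_list):
        raise ValueError("all regularization factors must be >= 0")
    problem, x0, scale = _prepare_problem(kspace, mask, coils, 0.0, dtype)
    L = estimate_lipschitz(problem.sens, problem.mask)
    prov = {"mask_seed": getattr(mask, "seed", None),
            "noise_seed": kspace.noise_seed}
    return [_solve(dataclasses.replace(problem, lam=float(lam)), x0, scale,
                   max_iter, tol, lipschitz=L, provenance=prov)
            for lam in lam_list]
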