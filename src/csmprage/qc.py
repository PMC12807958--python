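"""Image-quality metrics: tissue SNR, FWHM smoothness, 3D SSIM, difference maps.

These re-implement, on simulated volumes, the metric definitions used by
common neuroimaging QC pipelines: SNR as within-tissue-mask mean over
standard deviation; smoothness as the effective Gaussian FWHM implied by
the lag-one spatial autocorrelation of intensities (the classical
first-difference estimator); and the structural similarity index computed
with a 3D Gaussian window.  Tissue masks come from a simple 3-class
intensity clustering of in-brain voxels, so mask imperfection is part of
the metric, as it is in practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import (binary_closing, binary_fill_holes, binary_opening,
                           gaussian_filter)

__all__ = [
    "QCReport",
    "SSIMResult",
    "brain_mask",
    "tissue_snr",
    "segment_tissues_basic",
    "smoothness_fwhm",
    "ssim3d",
    "abs_difference",
    "FWHM_SENTINEL",
    "SNR_SENTINEL",
]

FWHM_SENTINEL = float("nan")   # autocorrelation at or below white-noise level
SNR_SENTINEL = float("inf")    # zero within-mask standard deviation


@dataclass
class QCReport:
    snr_gm: float
    snr_wm: float
    fwhm_x: float
    fwhm_y: float
    fwhm_z: float
    fwhm_combined: float
    fwhm_combined_mm: float
    image_id: str = ""


@dataclass
class SSIMResult:
    mean_ssim: float
    window_sigma: float
    K1: float
    K2: float
    dynamic_range: float


def brain_mask(image: np.ndarray, threshold_frac: float = 0.12) -> np.ndarray:
    """Head mask by intensity threshold plus morphological cleanup.

    The threshold is ``threshold_frac`` of the robust maximum (99.5th
    percentile), which separates CSF (~0.15 of WM) from background noise.
    """
    img = np.asarray(image, dtype=float)
    thr = threshold_frac * np.percentile(img, 99.5)
    m = img > thr
    m = binary_opening(m, iterations=1)
    m = binary_closing(m, iterations=1)
    return binary_fill_holes(m)


def tissue_snr(image: np.ndarray, tissue_mask: np.ndarray) -> float:
    """Mean signal in the tissue mask divided by its standard deviation.

    The sd uses the n-1 denominator.  A constant (zero-sd) region returns
    an infinite-SNR sentinel rather than raising.
    """
    m = np.asarray(tissue_mask, dtype=bool)
    n = int(np.count_nonzero(m))
    if n < 2:
        raise ValueError("tissue mask must contain at least 2 voxels")
    vals = np.asarray(image, dtype=float)[m]
    sd = float(np.std(vals, ddof=1))
    if sd == 0.0:
        return SNR_SENTINEL
    return float(np.mean(vals)) / sd


def _kmeans_1d(values: np.ndarray, init: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Deterministic 1D Lloyd iteration from fixed initial centroids."""
    centers = init.astype(float).copy()
    for _ in range(max_iter):
        edges = (centers[:-1] + centers[1:]) / 2.0
        assign = np.searchsorted(edges, values)
        new = np.array([values[assign == k].mean() if np.any(assign == k) else centers[k]
                        for k in range(len(centers))])
        if np.allclose(new, centers, rtol=0, atol=1e-12):
            break
        centers = new
    centers.sort()
    edges = (centers[:-1] + centers[1:]) / 2.0
    return np.searchsorted(edges, values)


def segment_tissues_basic(image: np.ndarray, mask: np.ndarray | None = None
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Basic 3-class tissue segmentation of in-brain intensities.

    One-dimensional k-means with centroids initialized at the 10th/50th/90th
    intensity percentiles; classes ordered by centroid give (CSF, GM, WM)
    masks.  Deterministic: identical images yield identical masks.
    """
    img = np.asarray(image, dtype=float)
    if mask is None:
        mask = brain_mask(img)
    vals = img[mask]
    if vals.size < 3 or np.unique(vals).size < 3:
        raise ValueError("need at least 3 distinct in-brain intensities")
    init = np.percentile(vals, [10, 50, 90])
    if np.unique(init).size < 3:
        raise ValueError("degenerate intensity histogram")
    assign = _kmeans_1d(vals, init)
    out = []
    for k in range(3):
        m = np.zeros(img.shape, dtype=bool)
        m[mask] = assign == k
        out.append(m)
    csf, gm, wm = out
    return gm, wm, csf


def _axis_rho(img: np.ndarray, mask: np.ndarray, axis: int, v: float) -> float:
    """Lag-one autocorrelation along an axis from within-mask differences."""
    m1 = mask & np.roll(mask, -1, axis=axis)
    m1 = m1.take(range(img.shape[axis] - 1), axis=axis)
    d = np.diff(img, axis=axis)[m1]
    if d.size < 2:
        return np.nan
    dv = float(np.var(d))
    return 1.0 - dv / (2.0 * v)


def smoothness_fwhm(image: np.ndarray, mask: np.ndarray,
                    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
                    ) -> tuple[float, float, float, float, float]:
    """Effective Gaussian FWHM of the image's spatial autocorrelation.

    Per axis a: rho_a = 1 - Var(first differences)/(2 Var(values)), and
    FWHM_a = sqrt(-2 ln 2 / ln rho_a) voxels for 0 < rho_a < 1 (the value
    a Gaussian-smoothed white-noise field of that FWHM would give).  The
    combined value is the geometric mean over axes; a NaN sentinel marks
    fields at or below white-noise correlation.  Returns
    (fwhm_x, fwhm_y, fwhm_z, combined_voxels, combined_mm).
    """
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if np.count_nonzero(m) < 100:
        raise ValueError("mask must contain at least 100 voxels")
    idx = np.where(m)
    if any(ix.max() - ix.min() < 2 for ix in idx):
        raise ValueError("mask must span at least 3 voxels per axis")
    v = float(np.var(img[m]))
    if v == 0:
        raise ValueError("image is constant inside the mask")

    fwhms = []
    for ax in range(3):
        rho = _axis_rho(img, m, ax, v)
        if not np.isfinite(rho) or rho <= 0 or rho >= 1:
            if np.isfinite(rho) and rho <= 0:
                warnings.warn("field rougher than white noise along axis "
                              f"{ax}; FWHM set to sentinel", RuntimeWarning)
            fwhms.append(FWHM_SENTINEL)
        else:
            fwhms.append(float(np.sqrt(-2.0 * np.log(2.0) / np.log(rho))))
    combined = float(np.prod(fwhms) ** (1.0 / 3.0)) if np.all(np.isfinite(fwhms)) else FWHM_SENTINEL
    mm = combined * float(np.prod(voxel_size_mm)) ** (1.0 / 3.0)
    return fwhms[0], fwhms[1], fwhms[2], combined, mm


def ssim3d(a: np.ndarray, b: np.ndarray, window_sigma: float = 1.5,
           K1: float = 0.01, K2: float = 0.03,
           mask: np.ndarray | None = None) -> SSIMResult:
    """Mean structural similarity between two volumes.

    Local statistics use a Gaussian window (sigma in voxels, truncated at
    3 sigma); the luminance/contrast constants are C1 = (K1 L)^2 and
    C2 = (K2 L)^2 with L the dynamic range (maximum over both volumes).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("volumes must have identical shapes")
    L = float(max(a.max(), b.max()))
    if L <= 0:
        raise ValueError("dynamic range must be positive")
    C1 = (K1 * L) ** 2
    C2 = (K2 * L) ** 2

    def filt(x):
        return gaussian_filter(x, window_sigma, truncate=3.0)

    mu_a, mu_b = filt(a), filt(b)
    var_a = filt(a * a) - mu_a ** 2
    var_b = filt(b * b) - mu_b ** 2
    cov = filt(a * b) - mu_a * mu_b
    ssim_map = ((2 * mu_a * mu_b + C1) * (2 * cov + C2)) / (
        (mu_a ** 2 + mu_b ** 2 + C1) * (var_a + var_b + C2))
    mean = float(ssim_map[mask].mean()) if mask is not None else float(ssim_map.mean())
    return SSIMResult(mean_ssim=mean, window_sigma=window_sigma,
                      K1=K1, K2=K2, dynamic_range=L)


def abs_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Voxelwise absolute difference |a - b| between two reconstructions.

    Intended for pairs reconstructed from the identical k-space at adjacent
    regularization settings, where the difference isolates what the
    regularization added or removed.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("volumes must have identical shapes")
    return np.abs(a - b)
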