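"""Synthetic digital brain phantom and multi-coil k-space simulation.

The phantom stands in for a 1 mm-isotropic T1-weighted human acquisition:
a white-matter core bounded by a star-shaped surface, a cortical gray-matter
ribbon of known regional thickness, a CSF shell, and ellipsoidal subcortical
nuclei of intermediate intensity embedded in the white matter.  T1 contrast
is modeled by fixed nominal tissue intensities (no Bloch simulation): the
intensity ordering WM > subcortical > GM > CSF > background is what drives
every downstream metric.

The forward model produces per-coil complex k-space as the (unnormalized)
3D DFT of bias-field x intensity x coil-sensitivity, plus i.i.d. circular
complex Gaussian noise.  The readout direction is array axis 0; the two
phase-encode directions (ky, kz) are axes 1 and 2, stored with DC at the
grid center so a 2D sampling mask multiplies in directly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Phantom",
    "CoilSet",
    "BiasField",
    "AcquisitionParams",
    "KSpaceData",
    "make_phantom",
    "make_coils",
    "make_bias_field",
    "simulate_kspace",
    "apply_sampling_mask",
    "noise_sd_for_target_snr",
    "PlacementError",
    "GeometryError",
]

# Tissue label codes.
LABEL_BACKGROUND = 0
LABEL_CSF = 1
LABEL_GM = 2
LABEL_WM = 3
LABEL_STRUCT0 = 4  # first subcortical structure; others follow consecutively

# Nominal T1w tissue intensities (arbitrary units).  Subcortical nuclei are
# assigned intermediate values between GM and WM (see make_phantom).
DEFAULT_INTENSITIES = {"wm": 1.00, "gm": 0.65, "csf": 0.15, "background": 0.0}
SUBCORTICAL_RANGE = (0.68, 0.76)
# Octant assignment order for structure placement: antipodal pairs first.
_OCTANT_ORDER = (0, 7, 3, 4, 5, 2, 6, 1)
# Per-octant cortical ribbon thickness (mm) of the default phantom.
DEFAULT_THICKNESS_MM = (3.2, 4.6, 3.6, 4.8, 4.0, 3.4, 4.4, 3.8)


class PlacementError(RuntimeError):
    """A subcortical structure could not be placed without overlap."""


class GeometryError(ValueError):
    """The requested grid is too small to contain the ribbon geometry."""


@dataclass
class Phantom:
    """Voxelized tissue labels, intensities and ground-truth bookkeeping."""

    label_volume: np.ndarray          # int16, 0=bg 1=CSF 2=GM 3=WM 4..=structures
    intensity_volume: np.ndarray      # float64, nominal tissue means
    structures: pd.DataFrame          # structure_id,name,cx,cy,cz,ax,ay,az,intensity,vol_vox,vol_mm3
    ribbon_spec: dict                 # inner/outer radii parameters + per-region thickness (mm)
    voxel_size_mm: tuple[float, float, float]
    seed: int

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.label_volume.shape

    def brain_mask(self) -> np.ndarray:
        """All voxels inside the head (any non-background label)."""
        return self.label_volume != LABEL_BACKGROUND

    def tissue_mask(self, label: int) -> np.ndarray:
        return self.label_volume == label

    def recompute_volumes(self) -> pd.DataFrame:
        """Ground-truth structure volumes recounted from the label volume."""
        vv = float(np.prod(self.voxel_size_mm))
        rows = []
        for _, s in self.structures.iterrows():
            n = int(np.count_nonzero(self.label_volume == s.structure_id))
            rows.append((int(s.structure_id), n, n * vv))
        return pd.DataFrame(rows, columns=["structure_id", "vol_vox", "vol_mm3"])


@dataclass
class CoilSet:
    """Complex receive-coil sensitivity maps.

    ``sensitivities`` has shape (n_coils, nx, ny, nz).  When ``normalized``
    the maps are divided by their voxelwise root-sum-of-squares so that
    RSS == 1 everywhere (the usual convention for estimated maps).
    """

    sensitivities: np.ndarray
    n_coils: int
    centers: np.ndarray
    width: float
    normalized: bool = True

    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.sensitivities) ** 2, axis=0))


@dataclass
class BiasField:
    """Smooth multiplicative intensity non-uniformity field, mean 1 in-brain."""

    field: np.ndarray
    amplitude: float
    seed: int


@dataclass
class AcquisitionParams:
    """Protocol metadata mirroring an ADNI-3-style MPRAGE acquisition."""

    matrix: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    TR_ms: float = 2300.0
    TI_ms: float = 900.0
    TE_ms: float = 2.9
    turbo_factor: int = 192
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.turbo_factor < 1:
            raise ValueError("turbo_factor must be >= 1")
        if any(m < 8 for m in self.matrix):
            raise ValueError("matrix dimensions must be >= 8")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class KSpaceData:
    """Per-coil complex 3D k-space (readout x ky x kz, DC of ky/kz centered)."""

    data: np.ndarray                  # (n_coils, nx, ny, nz) complex
    params: AcquisitionParams
    mask: object | None = None        # SamplingMask once under-sampled
    noise_seed: int = 0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


def _radial_coords(shape: tuple[int, int, int]) -> tuple[np.ndarray, ...]:
    c = [(n - 1) / 2.0 for n in shape]
    x, y, z = np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")
    dx, dy, dz = x - c[0], y - c[1], z - c[2]
    r = np.sqrt(dx * dx + dy * dy + dz * dz)
    with np.errstate(invalid="ignore"):
        theta = np.arccos(np.clip(np.divide(dz, r, out=np.zeros_like(r), where=r > 0), -1, 1))
    phi = np.arctan2(dy, dx)
    return dx, dy, dz, r, theta, phi


def _surface_perturbation(theta: np.ndarray, phi: np.ndarray, rng: np.random.Generator,
                          amplitude: float = 0.06, fold_amplitude: float = 0.025
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Star-shaped radial modulation: low-order shape + gyral-scale folding.

    The low-order terms give the brain an asymmetric overall shape; the
    higher-order terms emulate cortical folding, which is what puts
    fine-scale edge energy into the image (and hence makes under-sampling
    artifacts grow with acceleration, as on real anatomy).
    """
    basis = [
        np.sin(theta) * np.cos(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(theta),
        np.sin(theta) ** 2 * np.cos(2 * phi),
        np.sin(2 * theta) * np.sin(phi),
    ]  # overall head shape
    folds = [
        np.sin(theta) ** 3 * np.cos(5 * phi),
        np.sin(theta) ** 3 * np.sin(7 * phi),
        np.sin(4 * theta) * np.cos(3 * phi),
        np.sin(6 * theta) * np.sin(2 * phi),
        np.sin(theta) ** 2 * np.cos(9 * phi),
        np.sin(5 * theta) * np.cos(6 * phi),
    ]
    coeffs = np.concatenate([
        rng.uniform(-amplitude, amplitude, size=len(basis)),
        rng.uniform(-fold_amplitude, fold_amplitude, size=len(folds)),
    ])
    p = np.zeros_like(theta)
    for c, b in zip(coeffs, basis + folds):
        p += c * b
    pmax = float(np.max(np.abs(p)))
    if pmax > 0.12:  # keep the surface comfortably star-shaped and in-grid
        p *= 0.12 / pmax
    return p, coeffs


def _octant_regions(shape: tuple[int, int, int]) -> np.ndarray:
    """Angular octant index (0..7) of every voxel around the grid center."""
    dx, dy, dz, _, _, _ = _radial_coords(shape)
    return ((dx >= 0).astype(int) * 4 + (dy >= 0).astype(int) * 2
            + (dz >= 0).astype(int)).astype(np.int8)


def make_phantom(shape: tuple[int, int, int] = (96, 96, 96),
                 n_structures: int = 5,
                 seed: int = 0,
                 *,
                 voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
                 thickness_mm: float | np.ndarray | None = None,
                 csf_thickness_mm: float = 2.0,
                 intensities: dict | None = None,
                 surface_amplitude: float = 0.06,
                 fold_amplitude: float = 0.025,
                 texture_amplitude: float = 0.05,
                 texture_scale_vox: float = 1.5,
                 structure_semiaxis_range: tuple[float, float] | None = None,
                 depth_margin_vox: float | None = None) -> Phantom:
    """Build the deterministic digital brain phantom.

    The cortical ribbon is the shell between two star-shaped surfaces
    r_inner(theta, phi) and r_outer = r_inner + t(theta, phi), with the
    thickness t constant within each of 8 angular octants (``thickness_mm``
    may be a scalar or an array of 8 per-region values).  Subcortical nuclei
    are non-overlapping ellipsoids placed fully inside the white matter.

    Gyral-scale surface folding (``fold_amplitude``) and a smooth
    multiplicative intra-tissue texture (``texture_amplitude``, correlation
    length ``texture_scale_vox``) emulate the fine structure of real
    anatomy: they are what makes under-sampling artifacts and measured
    tissue SNR respond to acceleration the way scanner images do.  Nominal
    tissue means are unchanged by the zero-mean texture.
    """
    shape = tuple(int(n) for n in shape)
    if any(n < 32 for n in shape):
        raise GeometryError("phantom grid must be at least 32 voxels per axis")
    if n_structures < 0:
        raise ValueError("n_structures must be >= 0")
    vox = tuple(float(v) for v in voxel_size_mm)
    if len(set(vox)) != 1:
        raise GeometryError("only isotropic voxels are supported")
    vmm = vox[0]

    inten = dict(DEFAULT_INTENSITIES)
    if intensities:
        inten.update(intensities)

    if thickness_mm is None:
        # region-varying ribbon, like real cortex: gives the regional
        # thickness table genuine across-region variance
        thickness_mm = DEFAULT_THICKNESS_MM
    thickness = np.broadcast_to(np.asarray(thickness_mm, dtype=float), (8,)).copy()
    if np.any(thickness <= 0):
        raise GeometryError("ribbon thickness must be positive")

    rng = np.random.default_rng(seed)
    dx, dy, dz, r, theta, phi = _radial_coords(shape)
    pert, pert_coeffs = _surface_perturbation(theta, phi, rng, surface_amplitude,
                                              fold_amplitude)

    nmin = min(shape)
    # largest WM radius that keeps ribbon + CSF inside the grid even at the
    # maximum surface perturbation (15%), capped at 30% of the grid
    shell_vox = (float(np.max(thickness)) + csf_thickness_mm) / vmm
    r_inner_base = min(0.30 * nmin, (0.5 * nmin - 2.0 - shell_vox) / 1.15)
    if r_inner_base < 4.0:
        raise GeometryError("grid too small to contain ribbon + CSF shell")
    octant = _octant_regions(shape)
    t_vox = thickness[octant] / vmm

    r_inner = r_inner_base * (1.0 + pert)
    r_outer = r_inner + t_vox
    r_csf = r_outer + csf_thickness_mm / vmm
    if float(np.max(r_csf)) > 0.5 * nmin - 1.5:
        raise GeometryError("grid too small to contain ribbon + CSF shell")

    labels = np.zeros(shape, dtype=np.int16)
    labels[r <= r_csf] = LABEL_CSF
    labels[r <= r_outer] = LABEL_GM
    labels[r <= r_inner] = LABEL_WM

    # Subcortical ellipsoids, entirely inside WM with a 2-voxel safety margin.
    if structure_semiaxis_range is None:
        structure_semiaxis_range = (max(2.5, 0.052 * nmin), max(3.4, 0.080 * nmin))
    lo_ax, hi_ax = structure_semiaxis_range
    if depth_margin_vox is None:
        depth_margin_vox = max(2.0, 0.0625 * nmin)
    inner_min = float(np.min(r_inner))
    placed: list[tuple[np.ndarray, float]] = []
    rows = []
    all_axes = rng.uniform(lo_ax, hi_ax, size=(n_structures, 3))
    order = np.argsort(-all_axes.max(axis=1), kind="stable")  # largest first
    all_axes = all_axes[order]
    for k in range(n_structures):
        sid = LABEL_STRUCT0 + k
        if n_structures > 1:
            s_int = SUBCORTICAL_RANGE[0] + (SUBCORTICAL_RANGE[1] - SUBCORTICAL_RANGE[0]) * k / (n_structures - 1)
        else:
            s_int = 0.5 * sum(SUBCORTICAL_RANGE)
        axes = all_axes[k]
        amax = float(np.max(axes))
        ok = False
        # deep placement: keep the structure surface well clear of the
        # ribbon so reconstruction blur cannot bridge them; on cramped
        # grids the depth margin is relaxed stepwise before giving up
        margin = float(depth_margin_vox)
        while not ok and margin >= 1.0:
            max_center_r = inner_min - amax - margin
            if max_center_r <= 0:
                margin -= 1.0
                continue
            for _attempt in range(100):
                # direction biased toward a distinct octant per structure so
                # several structures pack without overlap; consecutive
                # (larger) structures get antipodal octants.  If the biased
                # tries fail, fall back to unbiased directions.
                oct_k = _OCTANT_ORDER[k % 8]
                base = np.array([1.0 if oct_k & 4 else -1.0,
                                 1.0 if oct_k & 2 else -1.0,
                                 1.0 if oct_k & 1 else -1.0]) / np.sqrt(3.0)
                if _attempt >= 50:
                    base = np.zeros(3)
                u = base + 0.35 * rng.normal(size=3)
                u /= np.linalg.norm(u)
                rad = max_center_r * rng.uniform(0.7, 1.0) ** (1 / 3)
                center = np.array([(n - 1) / 2.0 for n in shape]) + rad * u
                if all(np.linalg.norm(center - c0) > amax + a0 + 1.0 for c0, a0 in placed):
                    ok = True
                    break
            margin -= 1.0
        if not ok:
            raise PlacementError(f"could not place structure {k} after 100 attempts")
        placed.append((center, amax))
        e = (((dx + (shape[0] - 1) / 2.0 - center[0]) / axes[0]) ** 2
             + ((dy + (shape[1] - 1) / 2.0 - center[1]) / axes[1]) ** 2
             + ((dz + (shape[2] - 1) / 2.0 - center[2]) / axes[2]) ** 2) <= 1.0
        e &= labels == LABEL_WM  # never protrude outside WM
        labels[e] = sid
        nvox = int(np.count_nonzero(e))
        rows.append((sid, f"structure_{k:02d}", *center, *axes, s_int, nvox, nvox * vmm ** 3))

    structures = pd.DataFrame(
        rows, columns=["structure_id", "name", "cx", "cy", "cz",
                       "ax", "ay", "az", "intensity", "vol_vox", "vol_mm3"])

    intensity = np.zeros(shape, dtype=float)
    intensity[labels == LABEL_CSF] = inten["csf"]
    intensity[labels == LABEL_GM] = inten["gm"]
    intensity[labels == LABEL_WM] = inten["wm"]
    for _, s in structures.iterrows():
        intensity[labels == s.structure_id] = s.intensity

    if texture_amplitude > 0:
        from scipy.ndimage import gaussian_filter

        tex = gaussian_filter(rng.normal(size=shape), texture_scale_vox, mode="wrap")
        tex *= texture_amplitude / max(float(tex.std()), 1e-30)
        intensity *= np.where(labels != LABEL_BACKGROUND, 1.0 + tex, 1.0)

    ribbon_spec = {
        "r_inner_base_vox": r_inner_base,
        "perturbation_coeffs": pert_coeffs.tolist(),
        "surface_amplitude": surface_amplitude,
        "thickness_mm": thickness.tolist(),
        "csf_thickness_mm": csf_thickness_mm,
        "n_regions": 8,
    }
    return Phantom(labels, intensity, structures, ribbon_spec, vox, seed)


def make_coils(shape: tuple[int, int, int], n_coils: int = 8, seed: int = 0,
               *, width: float | None = None, flat: bool = False,
               normalize: bool = True) -> CoilSet:
    """Smooth complex coil sensitivity maps centered on a ring of points.

    Each coil magnitude is a broad Gaussian of a coil-center distance plus a
    floor (so the raw root-sum-of-squares never collapses), with a gentle
    linear phase ramp.  With ``normalize`` the maps are scaled to unit RSS.
    ``flat`` overrides everything with identically-1 sensitivities.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    shape = tuple(int(n) for n in shape)
    if flat:
        sens = np.ones((n_coils,) + shape, dtype=complex) / (np.sqrt(n_coils) if normalize else 1.0)
        return CoilSet(sens, n_coils, np.zeros((n_coils, 3)), 0.0, normalized=normalize)

    rng = np.random.default_rng(seed)
    nmin = min(shape)
    if width is None:
        width = 0.9 * nmin
    c = np.array([(n - 1) / 2.0 for n in shape])
    ring_r = 0.65 * nmin
    grids = np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")

    sens = np.empty((n_coils,) + shape, dtype=complex)
    centers = np.empty((n_coils, 3))
    for i in range(n_coils):
        ang = 2 * np.pi * i / n_coils + rng.uniform(-0.2, 0.2)
        zoff = rng.uniform(-0.25, 0.25) * nmin
        center = c + ring_r * np.array([np.cos(ang), np.sin(ang), 0.0]) + np.array([0, 0, zoff])
        centers[i] = center
        d2 = sum((g - cc) ** 2 for g, cc in zip(grids, center))
        # floor keeps raw RSS healthy everywhere; 1/sqrt(n) keeps it near 1
        mag = (0.25 + np.exp(-d2 / (2 * width ** 2))) / np.sqrt(n_coils)
        ramp = rng.uniform(-1, 1, size=3) * (np.pi / (2 * nmin))
        phase = sum(k * (g - cc) for k, g, cc in zip(ramp, grids, c * 0 + center))
        sens[i] = mag * np.exp(1j * phase)

    if normalize:
        sens /= np.sqrt(np.sum(np.abs(sens) ** 2, axis=0))[None]
    return CoilSet(sens, n_coils, centers, float(width), normalized=normalize)


def make_bias_field(shape: tuple[int, int, int], amplitude: float = 0.2,
                    seed: int = 0, *, brain_mask: np.ndarray | None = None) -> BiasField:
    """Smooth multiplicative bias field in [1-a, 1+a], mean 1 inside the brain.

    Stand-in for residual B1 transmit/receive non-uniformity; because the
    field is known it can be divided out exactly, which is how the pipeline
    emulates an on-scanner pre-scan normalization.
    """
    from scipy.ndimage import gaussian_filter

    if not 0 <= amplitude < 1:
        raise ValueError("amplitude must be in [0, 1)")
    rng = np.random.default_rng(seed)
    g = rng.normal(size=shape)
    g = gaussian_filter(g, sigma=[n / 5.0 for n in shape], mode="wrap")
    g /= max(float(np.max(np.abs(g))), 1e-30)
    field = 1.0 + amplitude * g
    if brain_mask is not None and brain_mask.any():
        field /= float(np.mean(field[brain_mask]))
        field = np.clip(field, 1 - amplitude, 1 + amplitude)
    return BiasField(field, amplitude, seed)


def noise_sd_for_target_snr(phantom: Phantom, target_wm_snr: float = 18.0) -> float:
    """k-space noise sd giving the requested WM SNR in the full reconstruction.

    With unit-RSS coils and a 1/N inverse DFT, a per-component k-space noise
    sd of sigma_k yields image-domain noise sd sigma_k/sqrt(N) in the
    coil-combined image, so sigma_k = mu_WM * sqrt(N) / SNR_target.
    """
    if target_wm_snr <= 0:
        raise ValueError("target SNR must be positive")
    mu_wm = float(np.mean(phantom.intensity_volume[phantom.tissue_mask(LABEL_WM)]))
    n = float(np.prod(phantom.shape))
    return mu_wm * np.sqrt(n) / target_wm_snr


def simulate_kspace(phantom: Phantom, coils: CoilSet, bias: BiasField | None,
                    params: AcquisitionParams) -> KSpaceData:
    """Forward-simulate noisy multi-coil k-space.

    k_c = DFT3(bias * intensity * S_c) + noise, unnormalized forward DFT,
    with the ky/kz axes fftshifted so DC sits at (ny//2, nz//2).  Noise is
    i.i.d. circular complex Gaussian, sd = params.noise_sd per component.
    """
    shape = phantom.shape
    if tuple(params.matrix) != shape:
        raise ValueError(f"params.matrix {params.matrix} does not match phantom shape {shape}")
    if coils.sensitivities.shape[1:] != shape:
        raise ValueError("coil map shape does not match phantom")
    img = phantom.intensity_volume
    if bias is not None:
        if bias.field.shape != shape:
            raise ValueError("bias field shape does not match phantom")
        img = img * bias.field

    rng = np.random.default_rng(params.seed)
    nc = coils.n_coils
    data = np.empty((nc,) + shape, dtype=complex)
    for c in range(nc):
        k = np.fft.fftn(img * coils.sensitivities[c])
        k = np.fft.fftshift(k, axes=(1, 2))
        data[c] = k
    if params.noise_sd > 0:
        noise = rng.normal(scale=params.noise_sd, size=(2, nc) + shape)
        data += noise[0] + 1j * noise[1]
    return KSpaceData(data=data, params=params, mask=None, noise_seed=params.seed)


def apply_sampling_mask(kspace: KSpaceData, mask) -> KSpaceData:
    """Zero out unsampled (ky, kz) columns; returns a new KSpaceData."""
    m = np.asarray(mask.mask, dtype=bool)
    if m.shape != kspace.shape[1:]:
        raise ValueError("mask shape does not match k-space phase-encode grid")
    data = kspace.data * m[None, None, :, :]
    return KSpaceData(data=data, params=kspace.params, mask=mask,
                      noise_seed=kspace.noise_seed)


# ---------------------------------------------------------------------------
# External interfaces: NIfTI-1 volumes + CSV structure table


def save_phantom(phantom: Phantom, outdir: str | Path, *, bias: BiasField | None = None,
                 coils: CoilSet | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(phantom.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(phantom.label_volume.astype(np.int16), affine),
             outdir / "labels.nii.gz")
    nib.save(nib.Nifti1Image(phantom.intensity_volume.astype(np.float32), affine),
             outdir / "intensity.nii.gz")
    if bias is not None:
        nib.save(nib.Nifti1Image(bias.field.astype(np.float32), affine),
                 outdir / "bias.nii.gz")
    if coils is not None:
        mag = np.abs(coils.sensitivities).astype(np.float32)
        nib.save(nib.Nifti1Image(np.moveaxis(mag, 0, -1), affine),
                 outdir / "coil_magnitude.nii.gz")
    cols = ["structure_id", "name", "cx", "cy", "cz", "vol_vox", "vol_mm3"]
    phantom.structures[cols].to_csv(outdir / "structures.csv", index=False)
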