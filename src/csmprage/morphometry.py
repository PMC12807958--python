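"""Phantom-ground-truth morphometry proxy and agreement statistics.

A surface-based morphometry suite cannot run on a desk-scale phantom, so
structure volumes and ribbon thickness are estimated directly from the
reconstructed image using the phantom's known geometry as seeds:

* volumes — a region grown from each structure's known center over
  connected voxels whose intensity lies within a band around the
  structure's nominal intensity;
* thickness — for each of 8 angular octant regions, the mean over
  gray-matter ribbon voxels of (distance to white matter + distance to
  CSF/outside), from Euclidean distance transforms of the segmentation.

The agreement statistics mirror a test–retest study design: within-sequence
repeatability as a percent agreement between repeats, and between-sequence
agreement as the squared Pearson correlation of per-structure estimates
from an accelerated protocol versus a fully sampled reference.  Both accept
any table with (id, kind, estimate) columns, so externally derived tables
(e.g. parsed aseg.stats files) can be fed through the same operations.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, distance_transform_edt, gaussian_filter
from scipy.ndimage import label as ndimage_label

from .phantom import Phantom, _octant_regions
from .qc import brain_mask, segment_tissues_basic

__all__ = [
    "estimate_volumes",
    "estimate_thickness",
    "repeatability",
    "between_sequence_r2",
    "read_aseg_stats",
]

_STRUCT6 = np.zeros((3, 3, 3), dtype=bool)
_STRUCT6[1, 1, 1] = True
_STRUCT6[0, 1, 1] = _STRUCT6[2, 1, 1] = True
_STRUCT6[1, 0, 1] = _STRUCT6[1, 2, 1] = True
_STRUCT6[1, 1, 0] = _STRUCT6[1, 1, 2] = True


def _grow_region(band: np.ndarray, seed_idx: tuple[int, int, int],
                 cap: int) -> np.ndarray:
    """6-connected region growing from a seed, stopped at ``cap`` voxels."""
    region = np.zeros(band.shape, dtype=bool)
    if not band[seed_idx]:
        return region
    region[seed_idx] = True
    while True:
        grown = binary_dilation(region, structure=_STRUCT6, mask=band)
        n = int(grown.sum())
        if n == region.sum():
            break
        region = grown
        if n >= cap:
            break
    return region


def estimate_volumes(image: np.ndarray, structures: pd.DataFrame,
                     voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
                     wm_intensity: float = 1.0, band_frac: float = 0.5,
                     cap_factor: float = 3.0, presmooth_sigma: float = 0.5,
                     roi_factor: float | None = 1.5,
                     provenance: dict | None = None) -> pd.DataFrame:
    """Estimate subcortical structure volumes by seeded region growing.

    For each structure the region grows from the known center over voxels
    with |intensity - nominal| <= band_frac * |nominal - WM nominal|,
    capped at cap_factor times the ground-truth voxel count.  The image is
    lightly smoothed first (``presmooth_sigma`` voxels), standing in for
    the spatial regularization of the segmentation tools this proxy
    replaces; without it, voxel noise fragments the grown region.  An
    empty region (contrast lost, e.g. over-regularized reconstruction)
    yields a NaN missing-structure sentinel.
    """
    img = np.asarray(image, dtype=float)
    if presmooth_sigma > 0:
        img = gaussian_filter(img, presmooth_sigma)
    vv = float(np.prod(voxel_size_mm))
    rows = []
    for _, s in structures.iterrows():
        half = band_frac * abs(float(s.intensity) - wm_intensity)
        band = np.abs(img - float(s.intensity)) <= half
        center = tuple(int(round(c)) for c in (s.cx, s.cy, s.cz))
        seed = None
        if band[center]:
            seed = center
        else:  # tolerate a noisy center voxel: scan the 3x3x3 neighborhood
            for off in np.ndindex(3, 3, 3):
                cand = tuple(np.clip(c + o - 1, 0, n - 1)
                             for c, o, n in zip(center, off, img.shape))
                if band[cand]:
                    seed = cand
                    break
        if seed is None:
            est = np.nan
        else:
            if roi_factor is not None:
                # spatial prior: growth may not stray far from the known
                # structure extent (position/size knowledge, as in the
                # atlas-based segmentation this proxy stands in for)
                grids = np.ogrid[tuple(slice(0, n) for n in img.shape)]
                roi = sum(((g - c) / (a * roi_factor)) ** 2
                          for g, c, a in zip(grids, (s.cx, s.cy, s.cz),
                                             (s.ax, s.ay, s.az))) <= 1.0
                band = band & roi
            cap = int(cap_factor * s.vol_vox) if s.vol_vox > 0 else int(cap_factor * 100)
            region = _grow_region(band, seed, cap)
            n = int(region.sum())
            est = n * vv if n > 0 else np.nan
        rows.append({"id": s["name"], "kind": "volume", "estimate": est})
    out = pd.DataFrame(rows)
    for k, v in (provenance or {}).items():
        out[k] = v
    return out


def estimate_thickness(image: np.ndarray, phantom: Phantom | None = None,
                       voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
                       presmooth_sigma: float = 0.0,
                       provenance: dict | None = None) -> pd.DataFrame:
    """Estimate regional cortical-ribbon thickness from an image.

    The GM ribbon comes from the basic tissue segmentation; per GM voxel
    the local thickness is (EDT distance to the nearest WM voxel) +
    (EDT distance to the nearest CSF/outside voxel) - 1 voxel, the 1-voxel
    term correcting for distances being measured between voxel centers
    rather than to the tissue boundaries.  Estimates are averaged within
    8 angular octants around the volume center.  Empty regions yield NaN.
    """
    img = np.asarray(image, dtype=float)
    if presmooth_sigma > 0:
        img = gaussian_filter(img, presmooth_sigma)
    bm = brain_mask(img)
    gm, wm, csf = segment_tissues_basic(img, bm)
    # Keep only the dominant connected GM component: subcortical nuclei of
    # GM-like intensity form interior islands that are not cortical ribbon.
    lab, nlab = ndimage_label(gm)
    if nlab > 1:
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        gm = lab == int(np.argmax(sizes))
    outside = csf | ~bm
    vmm = float(np.prod(voxel_size_mm)) ** (1.0 / 3.0)

    d_wm = distance_transform_edt(~wm)
    d_out = distance_transform_edt(~outside)
    local = (d_wm + d_out - 1.0) * vmm

    octants = _octant_regions(img.shape)
    rows = []
    for region in range(8):
        sel = gm & (octants == region)
        est = float(np.mean(local[sel])) if sel.any() else np.nan
        rows.append({"id": f"region_{region}", "kind": "thickness", "estimate": est})
    out = pd.DataFrame(rows)
    for k, v in (provenance or {}).items():
        out[k] = v
    return out


def _check_matched(t1: pd.DataFrame, t2: pd.DataFrame) -> pd.DataFrame:
    m = t1[["id", "kind", "estimate"]].merge(
        t2[["id", "kind", "estimate"]], on=["id", "kind"], suffixes=("_1", "_2"))
    if len(m) != len(t1) or len(m) != len(t2):
        raise ValueError("tables do not contain matching (id, kind) sets")
    return m


def repeatability(t1: pd.DataFrame, t2: pd.DataFrame) -> pd.DataFrame:
    """Per-structure test–retest repeatability in percent.

    repeatability = 100 * (1 - |e1 - e2| / ((e1 + e2)/2)): 100% for exact
    agreement, symmetric in its arguments and invariant to a common scale.
    """
    m = _check_matched(t1, t2)
    e1, e2 = m.estimate_1.to_numpy(float), m.estimate_2.to_numpy(float)
    mean = (e1 + e2) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        rep = 100.0 * (1.0 - np.abs(e1 - e2) / mean)
    return pd.DataFrame({"id": m.id, "kind": m.kind, "estimate_1": e1,
                         "estimate_2": e2, "repeatability_pct": rep})


def between_sequence_r2(ref_table: pd.DataFrame, cs_table: pd.DataFrame
                        ) -> pd.DataFrame:
    """Squared Pearson correlation across structures, per estimate kind.

    Answers how much of the variation across structures measured by the
    reference protocol is accounted for by the accelerated protocol.
    Requires at least 3 matched structures per kind; zero variance in
    either vector yields a NaN sentinel.
    """
    m = _check_matched(ref_table, cs_table)
    rows = []
    for kind, grp in m.groupby("kind", sort=True):
        e1, e2 = grp.estimate_1.to_numpy(float), grp.estimate_2.to_numpy(float)
        ok = np.isfinite(e1) & np.isfinite(e2)
        e1, e2 = e1[ok], e2[ok]
        if len(e1) < 3:
            raise ValueError(f"need >= 3 matched structures for kind {kind!r}")
        if np.std(e1) == 0 or np.std(e2) == 0:
            r2 = np.nan
        else:
            r2 = float(np.corrcoef(e1, e2)[0, 1] ** 2)
        rows.append({"kind": kind, "n_structures": len(e1), "r2": r2})
    return pd.DataFrame(rows)


def read_aseg_stats(path: str | Path) -> pd.DataFrame:
    """Parse a FreeSurfer aseg.stats-style whitespace table into a MorphTable.

    Keeps the structure name and Volume_mm3 columns, producing rows with
    (id, kind='volume', estimate) compatible with the agreement operations.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 5:
            continue
        rows.append({"id": parts[4], "kind": "volume", "estimate": float(parts[3])})
    if not rows:
        raise ValueError(f"no structure rows parsed from {path}")
    return pd.DataFrame(rows)
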