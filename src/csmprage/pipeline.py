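"""Experiment orchestration: the acceleration x regularization sweep.

``run_sweep`` mirrors the study design at desk scale: per session and
repeat it acquires one fully sampled reference and one CS acquisition per
acceleration factor (fresh noise and mask-jitter seeds each time),
retrospectively reconstructs every CS k-space at the full regularization
grid, and computes image-quality metrics, SSIM comparisons, morphometric
estimates and agreement statistics.  All outputs are tidy CSVs plus a
summary JSON; every row carries its provenance (session, repeat, R,
lambda, seeds) and the whole sweep is a pure function of the base seed.
"""

from __future__ import annotations

import dataclasses
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import morphometry, qc, recon, sampling
from .phantom import (AcquisitionParams, apply_sampling_mask, make_bias_field,
                      make_coils, make_phantom, noise_sd_for_target_snr,
                      simulate_kspace)

__all__ = ["SweepConfig", "run_sweep", "summarize_trends", "derive_seed"]

_CSV_FLOAT = "%.10g"


@dataclass
class SweepConfig:
    """Desk-scale sweep settings (defaults reproduce the study conditions)."""

    shape: tuple[int, int, int] = (96, 96, 96)
    accelerations: tuple[float, ...] = (1, 2, 4, 6, 8)
    regularizations: tuple[float, ...] = (0.0001, 0.0003, 0.0006, 0.0009, 0.0012)
    default_reg: float = 0.0003
    repeats: int = 2
    sessions: int = 2
    base_seed: int = 0
    n_coils: int = 4
    coil_width_frac: float = 0.35
    n_structures: int = 5
    target_wm_snr: float = 18.0
    bias_amplitude: float = 0.2
    turbo: int = 64
    density_exponent: float = 0.7
    jitter_deg: float = 20.0
    calib_radius: int = 6
    max_iter: int = 30
    tol: float = 0.0      # fixed iteration budget: same effort in every cell
    morph_regs: tuple[float, ...] = (0.0001, 0.0003, 0.0012)
    save_volumes: bool = False
    use_complex64: bool = True

    def __post_init__(self) -> None:
        if not self.accelerations or not self.regularizations:
            raise ValueError("acceleration and regularization lists must be non-empty")
        if self.repeats < 1 or self.sessions < 1:
            raise ValueError("repeats and sessions must be >= 1")
        if any(l < 0 for l in self.regularizations):
            raise ValueError("regularization factors must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "SweepConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "shape" in raw:
            raw["shape"] = tuple(raw["shape"])
        for k in ("accelerations", "regularizations", "morph_regs"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)


def derive_seed(base: int, *keys) -> int:
    """Stable child seed from a base seed and a path of labels/numbers.

    Adding new protocols to a sweep never perturbs the seeds of existing
    ones because each child depends only on its own key path.
    """
    ints = []
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()))
        else:
            ints.append(int(round(float(k) * 1000)))
    ss = np.random.SeedSequence(entropy=int(base), spawn_key=tuple(ints))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _qc_row(img: np.ndarray, voxel_mm, prov: dict) -> dict:
    bm = qc.brain_mask(img)
    gm, wm, csf = qc.segment_tissues_basic(img, bm)
    fx, fy, fz, fc, fmm = qc.smoothness_fwhm(img, bm, voxel_mm)
    return dict(prov, snr_gm=qc.tissue_snr(img, gm), snr_wm=qc.tissue_snr(img, wm),
                fwhm_x=fx, fwhm_y=fy, fwhm_z=fz, fwhm_vox=fc, fwhm_mm=fmm)


def _save_volume(vol: np.ndarray, voxel_mm, path: Path) -> None:
    import nibabel as nib
    affine = np.diag(list(voxel_mm) + [1.0])
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), path)


def run_sweep(config: SweepConfig, out_dir: str | Path) -> Path:
    """Run the full experiment; returns the output directory.

    Deterministic for a fixed ``config.base_seed``: repeated runs produce
    bit-identical CSV outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    dtype = np.complex64 if config.use_complex64 else np.complex128

    phantom = make_phantom(config.shape, config.n_structures,
                           seed=derive_seed(config.base_seed, "phantom"))
    coils = make_coils(config.shape, config.n_coils,
                       seed=derive_seed(config.base_seed, "coils"),
                       width=config.coil_width_frac * min(config.shape))
    bias = make_bias_field(config.shape, config.bias_amplitude,
                           seed=derive_seed(config.base_seed, "bias"),
                           brain_mask=phantom.brain_mask())
    noise_sd = noise_sd_for_target_snr(phantom, config.target_wm_snr)
    voxel_mm = phantom.voxel_size_mm
    n_ky, n_kz = config.shape[1], config.shape[2]

    qc_rows: list[dict] = []
    ssim_rows: list[dict] = []
    morph_tables: list[pd.DataFrame] = []
    errors: list[dict] = []
    # reference (fully sampled) images per (session, repeat), bias-corrected
    ref_imgs: dict[tuple[int, int], np.ndarray] = {}
    ref_morphs: dict[tuple[int, int], pd.DataFrame] = {}

    full = sampling.full_mask(n_ky, n_kz)
    cs_regs = sorted(set(config.regularizations))
    lam_lo = cs_regs[0]

    def morph(img, prov):
        vol = morphometry.estimate_volumes(img, phantom.structures, voxel_mm,
                                           provenance=prov)
        thk = morphometry.estimate_thickness(img, phantom, voxel_mm,
                                             provenance=prov)
        t = pd.concat([vol, thk], ignore_index=True)
        morph_tables.append(t)
        return t

    for s in range(1, config.sessions + 1):
        for t in range(1, config.repeats + 1):
            # --- fully sampled reference -------------------------------
            nseed = derive_seed(config.base_seed, "noise", s, t, 1)
            params = AcquisitionParams(matrix=config.shape, noise_sd=noise_sd,
                                       turbo_factor=config.turbo, seed=nseed)
            ks = apply_sampling_mask(
                simulate_kspace(phantom, coils, bias, params), full)
            ref = recon.zero_filled_recon(ks, coils)
            img_ref = ref.volume / bias.field
            prov = {"session": s, "repeat": t, "R": 1.0, "lam": 0.0,
                    "noise_seed": nseed, "jitter_seed": -1}
            ref_imgs[(s, t)] = img_ref
            qc_rows.append(_qc_row(img_ref, voxel_mm, prov))
            ref_morphs[(s, t)] = morph(img_ref, prov)
            if config.save_volumes:
                _save_volume(img_ref, voxel_mm, out / f"ref_s{s}r{t}.nii.gz")

            # --- CS protocols ------------------------------------------
            for R in config.accelerations:
                if R <= 1:
                    continue
                jseed = derive_seed(config.base_seed, "jitter", s, t, R)
                nseed = derive_seed(config.base_seed, "noise", s, t, R)
                try:
                    mask = sampling.phyllotaxis_mask(
                        n_ky, n_kz, R, turbo=config.turbo,
                        q=config.density_exponent, jitter=config.jitter_deg,
                        calib_radius=config.calib_radius, seed=jseed)
                    params = AcquisitionParams(
                        matrix=config.shape, noise_sd=noise_sd,
                        turbo_factor=config.turbo, seed=nseed)
                    ks = apply_sampling_mask(
                        simulate_kspace(phantom, coils, bias, params), mask)
                    vols = recon.retro_reconstruct(
                        ks, mask, coils, cs_regs, max_iter=config.max_iter,
                        tol=config.tol, dtype=dtype)
                except Exception as exc:  # record and continue the sweep
                    errors.append({"session": s, "repeat": t, "R": R,
                                   "error": repr(exc)})
                    continue
                img_lo = None
                for rv in vols:
                    img = rv.volume / bias.field
                    prov = {"session": s, "repeat": t, "R": float(R),
                            "lam": rv.lam, "noise_seed": nseed,
                            "jitter_seed": jseed}
                    qc_rows.append(_qc_row(img, voxel_mm, prov))
                    if rv.lam == lam_lo:
                        img_lo = img
                    if rv.lam == config.default_reg:
                        ssim_rows.append(dict(
                            prov, kind="vs_full",
                            ssim=qc.ssim3d(ref_imgs[(s, t)], img).mean_ssim))
                    if rv.lam > lam_lo and img_lo is not None:
                        ssim_rows.append(dict(
                            prov, kind="vs_lowreg",
                            ssim=qc.ssim3d(img_lo, img).mean_ssim))
                    if rv.lam in config.morph_regs:
                        morph(img, prov)
                    if config.save_volumes:
                        _save_volume(img, voxel_mm,
                                     out / f"cs_s{s}r{t}_R{R}_lam{rv.lam}.nii.gz")

    qc_df = pd.DataFrame(qc_rows)
    ssim_df = pd.DataFrame(ssim_rows)
    morph_df = (pd.concat(morph_tables, ignore_index=True)
                if morph_tables else pd.DataFrame())

    agreement_df = _agreement_tables(morph_df, config)

    sort_qc = ["session", "repeat", "R", "lam"]
    qc_df.sort_values(sort_qc, inplace=True, ignore_index=True)
    ssim_df.sort_values(["kind"] + sort_qc, inplace=True, ignore_index=True)
    morph_df.sort_values(sort_qc + ["kind", "id"], inplace=True, ignore_index=True)

    qc_df.to_csv(out / "qc.csv", index=False, float_format=_CSV_FLOAT)
    ssim_df.to_csv(out / "ssim.csv", index=False, float_format=_CSV_FLOAT)
    morph_df.to_csv(out / "morph.csv", index=False, float_format=_CSV_FLOAT)
    agreement_df.to_csv(out / "agreement.csv", index=False, float_format=_CSV_FLOAT)

    summary = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "noise_sd": noise_sd,
        "n_images": len(qc_rows),
        "n_errors": len(errors),
        "errors": errors,
        "elapsed_s": round(time.time() - t_start, 1),
        "version": 1,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return out


def _agreement_tables(morph_df: pd.DataFrame, config: SweepConfig) -> pd.DataFrame:
    """Within-sequence repeatability and between-sequence R^2 tables.

    Repeatability: per (R, lambda, structure), all repeat pairs within a
    session, averaged over sessions.  Between-sequence R^2: each CS
    acquisition versus the same-numbered fully sampled repeat of the same
    session (four independent comparisons under the default design).
    """
    rows: list[dict] = []
    if morph_df.empty:
        return pd.DataFrame(rows)
    g = morph_df.groupby(["session", "repeat", "R", "lam"])

    def table(s, t, R, lam):
        key = (s, t, float(R), float(lam))
        return g.get_group(key) if key in g.groups else None

    # --- repeatability across repeats, same protocol, same session
    for R in morph_df.R.unique():
        lams = morph_df.loc[morph_df.R == R, "lam"].unique()
        for lam in lams:
            per_struct: dict[tuple[str, str], list[float]] = {}
            for s in range(1, config.sessions + 1):
                for t1 in range(1, config.repeats + 1):
                    for t2 in range(t1 + 1, config.repeats + 1):
                        a, b = table(s, t1, R, lam), table(s, t2, R, lam)
                        if a is None or b is None:
                            continue
                        rep = morphometry.repeatability(a, b)
                        for _, r in rep.iterrows():
                            per_struct.setdefault((r.id, r.kind), []).append(
                                r.repeatability_pct)
            for (sid, kind), vals in per_struct.items():
                rows.append({"metric": "repeatability_pct", "R": float(R),
                             "lam": float(lam), "id": sid, "kind": kind,
                             "session": -1, "repeat": -1,
                             "value": float(np.nanmean(vals))})

    # --- between-sequence R^2 versus fully sampled reference
    for R in morph_df.R.unique():
        if R <= 1:
            continue
        for lam in morph_df.loc[morph_df.R == R, "lam"].unique():
            for s in range(1, config.sessions + 1):
                for t in range(1, config.repeats + 1):
                    ref = table(s, t, 1.0, 0.0)
                    cs = table(s, t, R, lam)
                    if ref is None or cs is None:
                        continue
                    r2 = morphometry.between_sequence_r2(ref, cs)
                    for _, r in r2.iterrows():
                        rows.append({"metric": "between_r2", "R": float(R),
                                     "lam": float(lam), "id": "all",
                                     "kind": r.kind, "session": s,
                                     "repeat": t, "value": r.r2})
    df = pd.DataFrame(rows)
    if not df.empty:
        df.sort_values(["metric", "R", "lam", "kind", "id", "session", "repeat"],
                       inplace=True, ignore_index=True)
    return df


def summarize_trends(experiment_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Aggregate a completed sweep into trend tables.

    Returns (and writes as CSVs): mean +/- SE of SSIM versus the fully
    sampled reference per R; mean SSIM versus the lowest-regularization
    reconstruction per (R, lambda); SNR and FWHM per (R, lambda); and the
    agreement summaries.
    """
    d = Path(experiment_dir)
    out: dict[str, pd.DataFrame] = {}
    ssim = pd.read_csv(d / "ssim.csv")
    qc_df = pd.read_csv(d / "qc.csv")
    agreement = pd.read_csv(d / "agreement.csv")

    vs_full = ssim[ssim.kind == "vs_full"]
    if len(vs_full):
        t1 = vs_full.groupby("R").ssim.agg(["mean", "sem", "count"]).reset_index()
        t1.columns = ["R", "ssim_mean", "ssim_se", "n"]
        out["ssim_vs_full"] = t1

    vs_low = ssim[ssim.kind == "vs_lowreg"]
    if len(vs_low):
        t2 = vs_low.groupby(["R", "lam"]).ssim.agg(["mean", "sem", "count"]).reset_index()
        t2.columns = ["R", "lam", "ssim_mean", "ssim_se", "n"]
        out["ssim_vs_lowreg"] = t2

    t3 = qc_df.groupby(["R", "lam"])[["snr_wm", "snr_gm", "fwhm_vox", "fwhm_mm"]]\
        .mean().reset_index()
    out["qc_trends"] = t3

    if len(agreement):
        rep = agreement[agreement.metric == "repeatability_pct"]
        if len(rep):
            out["repeatability"] = rep.groupby(["R", "lam", "kind"])\
                .value.agg(["mean", "min"]).reset_index()
        r2 = agreement[agreement.metric == "between_r2"]
        if len(r2):
            out["between_r2"] = r2.groupby(["R", "lam", "kind"])\
                .value.agg(["mean", "min"]).reset_index()

    for name, df in out.items():
        df.to_csv(d / f"summary_{name}.csv", index=False, float_format=_CSV_FLOAT)
    return out
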