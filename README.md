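# csmprage

Desk-scale simulation study of compressed-sensing (CS) accelerated MPRAGE
imaging for brain morphometry.  Structural T1-weighted MRI is slow
(~9 minutes fully sampled at 1 mm isotropic); CS acquisition shortens it
to 1–4 minutes by sampling only a fraction 1/R of the phase-encode plane
with an incoherent, variable-density pattern and reconstructing with
sparsity-regularized iterative optimization.  The open question for
morphometry users is what the two dials — the under-sampling factor R and
the reconstruction regularization factor Reg — cost in image quality and
in the stability of volume/thickness estimates.

This package re-creates that study end to end on a synthetic digital
brain, for researchers who want a controlled, fully reproducible test bed
rather than scanner data:

* **phantom** — labeled digital brain (WM core, folded GM ribbon of known
  regional thickness, CSF shell, subcortical nuclei of intermediate
  intensity), coil sensitivity maps, bias field, and noisy multi-coil
  k-space via the forward model k_c = DFT(bias · image · S_c) + noise;
* **sampling** — jittered variable-density spiral-phyllotaxis masks on
  the (ky, kz) grid (golden-angle 137.50776°, radial law r ∝ (m/M)^0.7,
  fully sampled calibration disc), turbo-factor shot structure with
  center-out symmetric ordering, PSF incoherence diagnostics, and an
  idealized scan-time estimate;
* **recon** — per-slice wavelet-regularized reconstruction
  min_x ½ Σ_c ‖M∘F(S_c∘x) − y_c‖² + λ‖Ψx‖₁ solved by FISTA
  (orthogonal db4 wavelets, magnitude soft-thresholding, fixed 1/L step),
  plus the zero-filled baseline and retrospective re-reconstruction of
  one k-space at several λ;
* **qc** — tissue SNR (mean/sd within segmented masks), FWHM smoothness
  from the lag-one spatial autocorrelation, 3D Gaussian-window SSIM,
  absolute-difference maps;
* **morphometry** — phantom-ground-truth proxies for subcortical volumes
  (seeded region growing) and regional ribbon thickness (distance
  transforms), with test–retest repeatability and between-sequence
  Pearson R² agreement statistics (FreeSurfer-style aseg.stats tables can
  be ingested for the agreement operations);
* **pipeline** — the full acceleration × regularization sweep with seed
  management, tidy CSV outputs and trend summaries, plus a thin
  `csmprage` CLI (`phantom`, `mask`, `sweep`, `summarize`).

## Worked example

`examples/03_cs_reconstruction.py` simulates one CSx6 acquisition of a
64³ phantom and re-reconstructs the identical k-space across the console
regularization grid:

```
CSx6 acquisition: achieved R = 5.96
zero-filled baseline reconstructed (max 1.27)

Reg=0.0001: WM SNR   9.0  GM SNR   6.0  FWHM 3.40 vox  objective 0.6 -> 0.40 (50 iters)
Reg=0.0003: WM SNR  12.0  GM SNR   7.0  FWHM 4.26 vox  objective 0.7 -> 0.58 (50 iters)
Reg=0.0006: WM SNR  13.3  GM SNR   7.0  FWHM 5.06 vox  objective 0.8 -> 0.75 (50 iters)
Reg=0.0009: WM SNR  13.7  GM SNR   7.0  FWHM 5.52 vox  objective 1.0 -> 0.87 (50 iters)
Reg=0.0012: WM SNR  13.8  GM SNR   7.0  FWHM 5.86 vox  objective 1.2 -> 0.98 (50 iters)
```

Raising Reg buys white-matter SNR at the price of smoothness (FWHM), the
trade-off a scanner operator navigates when picking the console value;
the gray-matter SNR barely moves.  `examples/02_sampling_masks.py` prints
the protocol-level view — the fully sampled 240×192 acquisition takes
552 s while the CSx6 mask needs 6,028 samples in 32 shots = 74 s (1:14)
with a PSF peak sidelobe of 0.31 versus 1.0 for coherent decimation — and
`examples/05_morphometry_agreement.py` shows repeatability and
between-sequence R² of the morphometric estimates.

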