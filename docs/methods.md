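# Methods

`csmprage` is a desk-scale, fully synthetic re-creation of a
compressed-sensing (CS) MPRAGE acceleration study: how do the
under-sampling factor R and the reconstruction regularization factor
(Reg, written λ below) trade off T1-weighted image quality and the
stability of morphometric estimates?  Everything runs from seeds; there is
no external data.  This note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## Digital phantom

The phantom (`make_phantom`) is a voxelized head on an isotropic grid
(default 96³ at a nominal 1 mm):

* a white-matter (WM) core bounded by a star-shaped surface
  r_inner(θ, φ) = r₀ · (1 + p(θ, φ)), where p combines low-order
  harmonics (overall head shape, amplitude 0.06) with higher-order terms
  emulating gyral-scale folding (amplitude 0.025, capped at ±12% total);
* a gray-matter (GM) ribbon between r_inner and
  r_outer = r_inner + t(θ, φ), with the thickness t constant within each
  of 8 angular octants.  The default profile varies across octants
  (3.2–4.8 mm, like real cortex) so regional thickness statistics have
  genuine across-region variance; a uniform ribbon can be requested;
* a 2 mm CSF shell outside the ribbon;
* ellipsoidal subcortical nuclei placed fully inside the WM, each with a
  distinct intermediate intensity.  Placement is deep (a grid-scaled
  margin from the ribbon, relaxed stepwise on cramped grids) and spread
  across octants so reconstruction blur cannot bridge structures to the
  ribbon or to one another.

T1 contrast is modeled by fixed nominal tissue means (WM 1.00,
subcortical 0.68–0.76, GM 0.65, CSF 0.15, background 0), not by solving
the Bloch equations: the acquisition protocol metadata (TR/TI/TE =
2300/900/2.9 ms) is carried but never enters the signal model, because
every downstream metric here depends on contrast ordering and geometry,
not on sequence physics.  Two realism terms matter materially: a smooth
multiplicative intra-tissue texture (5% sd, 1.5-voxel correlation length
— real FAST-masked WM intensity variation is of this order) and the
surface folding above.  They are what gives the image fine-scale
structure for under-sampling artifacts to act on; without them the
phantom is piecewise constant and almost nothing depends on R.

Ground truth is bookkept exactly: structure volumes are voxel counts of
the label volume, ribbon thickness is the construction parameter per
octant.

## Acquisition model

Per coil c, k-space is the unnormalized 3D DFT of
(bias field × intensity × S_c) plus i.i.d. circular complex Gaussian
noise (`simulate_kspace`); the inverse transform carries the 1/N factor.
The readout direction is axis 0; the (ky, kz) phase-encode plane is
stored with DC at the grid center so a 2D mask multiplies in directly.

Coil sensitivities (`make_coils`) are smooth complex profiles (Gaussian
magnitude of distance to a ring of coil centers with a floor, mild linear
phase ramps), RSS-normalized to 1 by default, as estimated maps would be.
Unit RSS makes the fully-sampled normal operator the identity, which in
turn makes the λ=0 full-sampling reconstruction exact by construction.

The multiplicative bias field (`make_bias_field`, ±20%, mean 1 in-brain)
stands in for B1-related intensity non-uniformity.  Because the simulated
field is known, the pipeline divides it out exactly before computing any
metric — the equivalent of the vendor pre-scan normalization being
treated as solved upstream.

The k-space noise level is parameterized by the target WM SNR of the
fully sampled reconstruction (default 18): with unit-RSS coils,
σ_k = μ_WM · √N / SNR_target.

## Sampling

`phyllotaxis_mask` builds the under-sampling pattern on the (ky, kz)
grid: M = round(footprint/R) candidates at golden-angle increments
(137.50776°) with uniform angular jitter (±20°) and radial law
r ∝ (m/M)^q, q = 0.7 (q > 0.5 is center-dense).  Candidates snap to the
nearest unsampled grid point inside an elliptical footprint (expanding
ring search on collision), so sample counts are exact; a fully sampled
calibration disc (radius 6) covers the center, and a two-pass count
adjustment keeps the achieved acceleration within 5% of the request.
Samples are partitioned into shots of at most `turbo` consecutive spiral
indices; each shot is reordered symmetrically so its most central sample
sits at the temporal middle (center-of-k-space at the center of the
trajectory time-wise).  Shot ordering is metadata: no signal evolution
along the readout train is simulated.

`estimate_scan_time` returns ceil(n_samples / turbo) × TR.  On the full
240×192 matrix at turbo 192 this lands within one TR of the published
protocol times for the fully sampled (552 s vs 9:14) and CS×2..×10
protocols; the vendor's exact shot-count rounding is not public, so the
estimate is documented as idealized and never tested for exact equality.

`mask_psf_metrics` (inverse-DFT point spread function, peak sidelobe
ratio) quantifies incoherence; phyllotaxis masks sit well below coherent
1-in-R decimation at every tested R.

## Reconstruction

After a 1D inverse DFT along the readout axis, each readout position is an
independent 2D problem

    min_x  1/2 Σ_c ‖M ∘ F(S_c ∘ x) − y_c‖₂² + λ‖Ψx‖₁

with F the unitary 2D DFT, M the mask, S_c the coil maps and Ψ an
orthogonal Daubechies-4 wavelet transform (4 levels, periodized; the
level count drops automatically when an axis stops being even).  All
slices are solved simultaneously as one batched array.

Solver: FISTA with a fixed 1/L step (L from 15 power iterations on the
normal operator, +1% safety; with unit-RSS coils L ≈ 1), magnitude
soft-thresholding at λ/L as the prox, 50 iterations default, stopping
early when the relative objective change falls below 1e-6.  The objective
is evaluated at every iterate at no extra FFT cost: the forward transform
of the fresh iterate is cached and the momentum point's transform is a
linear combination of the two cached ones.

λ scale.  The regularization factors are console-style dimensionless
numbers (1e-4..1.2e-3).  The data are normalized so the *mean per-slice
signal energy is one* before solving.  On that scale the ℓ1 term weighs a
few percent of the cost at the default λ = 3e-4: the default mildly
denoises, and 1.2e-3 visibly smooths — the operating regime reported for
scanner reconstructions.  (Normalizing to unit maximum instead makes the
entire λ grid numerically inert — the term weighs ~1e-5 of the cost — and
normalizing to unit total energy over-regularizes by an order of
magnitude; both were measured before fixing this convention.)

`retro_reconstruct` re-solves the identical k-space at a list of λ values
with a shared Lipschitz estimate, mirroring retrospective
re-reconstruction at the scanner console.  `zero_filled_recon` is the
unregularized baseline and the exact reconstruction for fully sampled
data.

In the sweep, reconstructions run the full 50-iteration budget (tol = 0)
so every (R, λ) cell receives identical solver effort, as a scanner's
fixed iterative reconstruction would.

## Image-quality metrics

* Tissue SNR: mean/sd (ddof 1) of intensities within a tissue mask.  The
  masks come from a deterministic 3-class 1D k-means segmentation of
  in-brain intensities (centroids initialized at the 10/50/90th
  percentiles), applied to the image under test — mask imperfection is
  part of the metric, as in QC practice.  A constant region returns an
  infinite-SNR sentinel.
* FWHM smoothness: per axis, ρ = 1 − Var(first differences)/(2 Var),
  FWHM = sqrt(−2 ln 2 / ln ρ) voxels for 0 < ρ < 1 (the width of the
  Gaussian kernel that would give white noise that lag-one correlation);
  combined value is the geometric mean, also reported in mm.  ρ ≤ 0
  (rougher than white noise) yields a NaN sentinel with a warning.  For
  pure i.i.d. noise the estimate collapses toward zero/sentinel rather
  than to a finite "intrinsic" width; kernel recovery for 2–6-voxel
  kernels is within ±15%.
* SSIM: local Gaussian window (σ = 1.5 voxels, truncated at 3σ), C1 =
  (0.01 L)², C2 = (0.03 L)², L = max over both volumes; mean over the
  volume or a mask.  No registration is performed — simulated volumes
  share a grid by construction.
* Absolute difference maps |a − b| for reconstructions of the identical
  k-space at adjacent λ.

## Morphometry proxy

A surface-based morphometry suite cannot run on a desk phantom, so the
estimators use the phantom's known geometry as seeds while measuring only
the reconstructed image:

* Volumes: region grown (6-connectivity) from the known center over
  voxels within ±0.5·|nominal − WM| of the structure's nominal intensity,
  after a light 0.5-voxel Gaussian pre-smooth (standing in for the
  spatial regularization of real segmentation tools; without it voxel
  noise fragments the region).  Growth is confined to the structure's
  ellipsoid dilated 1.5× — the position/size prior that atlas-based
  segmentation brings — and capped at 3× the true voxel count.  An empty
  region returns a NaN missing-structure sentinel (this is what happens
  when over-regularization washes out subcortical contrast).
* Thickness: per angular octant, the mean over cortical-ribbon GM voxels
  of (EDT distance to WM + EDT distance to CSF/outside − 1 voxel); the
  −1 corrects center-to-center distances to boundary distances.  Interior
  GM-intensity islands (the nuclei) are excluded by keeping only the
  dominant connected GM component.  Oblique folded surfaces bias the
  estimate low by ~0.3–0.4 mm at the default folding amplitude; recovery
  stays within the 0.5 mm tolerance on noise-free references.

Agreement statistics: within-sequence repeatability per structure,
100·(1 − |e₁ − e₂| / mean) — the percent-agreement form; the underlying
study never printed its formula, so this definition is this package's
and is used consistently — and between-sequence agreement as the squared
Pearson correlation across structures between an accelerated protocol and
the fully sampled reference, computed separately for volumes and
thickness.  `read_aseg_stats` ingests FreeSurfer-style whitespace tables
so the agreement operations also run on real segmentation output.

## Sweep design and problem sizes

`run_sweep` mirrors the in-vivo design at desk scale: per session (2) and
repeat (2), one fully sampled reference plus one CS acquisition per
R ∈ {2, 4, 6, 8}, each with fresh noise and jitter seeds; every CS
k-space retrospectively reconstructed at λ ∈ {1, 3, 6, 9, 12}·1e-4 —
84 reconstructions at 96³ with 4 receive channels, complex64 arithmetic
and a fixed 30-iteration solver budget, about 8 minutes on one CPU.
(The in-vivo study used 4 repeats per CS protocol and a 256×240×192
matrix with a 32-channel coil; the desk defaults keep every trend at ~1%
of the compute.  The 30-iteration budget was checked against 50 and 400
iterations: the reported metrics agree to better than 2%, i.e. the solver
is converged well before the budget.)  QC and SSIM run at all λ; morphometry at
λ ∈ {low, default, high}, mirroring the low/default/high regularization
comparisons of the underlying design.  Child seeds derive from
SeedSequence(base, key-path), so adding protocols never perturbs existing
ones; outputs are tidy CSVs with full provenance and the whole sweep is
bit-reproducible from the base seed.

## What the synthetic conditions do and do not show

The simulation reproduces, and the test suite asserts: the λ-direction
trade-off (raising Reg raises WM SNR and FWHM smoothness at fixed R, most
strongly at high R), the SSIM ordering of reconstructions from identical
k-space across the λ grid (strictly decreasing in λ at every R), the SNR
drop from the fully sampled reference to any CS protocol, and the
stability of morphometric estimates (repeatability > 90%,
between-sequence volume R² ≥ 0.9 up to R = 8).

Two in-vivo regularities are *not* reachable at desk scale, for one
shared reason.  With a center-dense trajectory at desk-scale sample
counts (~10³ phase encodes rather than ~10⁴–10⁵), higher R removes noisy
high-frequency samples and the wavelet-ℓ1 minimizer prunes the weakly
determined detail, so the R = 8 reconstruction is smoother — hence
cleaner, and more similar to every other reconstruction.  Consequently
(i) the monotone decline of WM SNR across CS factors 2→8 at fixed
default λ inverts at the tail (the R = 1 → R ≥ 2 drop does reproduce;
verified to be a property of the converged minimizer, not of the
iteration budget), and (ii) the SSIM orderings *across R* (similarity to
the fully sampled reference falling with R, and λ-sensitivity of the
reconstruction growing with R) flatten or turn U-shaped even though the
orderings *across λ* are strict at every R.  The in-vivo mechanism
pulling the other way — g-factor noise amplification of a
sharpness-restoring 32-channel reconstruction — requires sample counts
and coil arrays outside the desk regime.

Other known limitations: no skull/scalp, motion, or susceptibility
effects; no Bloch-level MPRAGE signal (no flip angle or echo spacing is
modeled); shot ordering carries no signal evolution; the morphometry
proxy is not a surface pipeline and its absolute estimates carry small
geometric biases (documented above) that cancel in the agreement
statistics.
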