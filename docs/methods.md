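# Methods

This note documents the models, estimators and numerical choices behind
`afshear`, what the synthetic generator does and does not emulate, and the
limits of what passing tests demonstrate.

## Constitutive model and mechanical simulation

Simulated tissue is a linear generalized-Maxwell (Prony) solid with
relaxation modulus

    G(t) = G_eq + Σ_i G_i exp(−t/τ_i),     G_eq > 0, G_i ≥ 0, τ_i > 0,

which is non-increasing by construction.  The model was chosen because
every quantity the pipelines report — loss tangent, storage/loss/dynamic
moduli, hysteresis, equilibrium stress, stress relaxation — has a closed
form under it, so estimators can be validated against independent oracles.
The single-branch special case (standard linear / Zener solid) is the
oracle fixture of the test suite:

    G′(ω) = G_eq + G₁ω²τ²/(1+ω²τ²),   G″(ω) = G₁ωτ/(1+ω²τ²),
    tan δ = G″/G′,   loop area = π F₀ d₀ sin δ.

Real annulus fibrosus is nonlinear, anisotropic and poroelastic at large
strain; none of that is modelled.  In particular a linear solid never
leaves its "neutral zone", so trilinear fits on simulated 40%-strain loops
degenerate by design and the neutral-zone fitter is validated on
constructed piecewise-linear ground truth instead.

**Default branch parameterisation.**  Soft fibrocartilage shows a nearly
flat loss tangent across the tested decades (≈0.16–0.18), which no single
Maxwell branch can reproduce (one branch gives tan δ ∝ 1/ωτ away from its
peak).  `default_branches_for(G_eq)` therefore places one branch per
tested frequency (τ_j = 1/2πf_j at 0.01, 0.1, 1 Hz) and solves the 3×3
linear system that makes the closed-form loss tangent hit the targets
(0.18, 0.16, 0.16) exactly.  All branch times are ≤ 16 s, so 20-minute
holds relax fully (> 75 τ).

**Time stepping.**  For piecewise-linear strain each branch admits the
exact exponential update q[n] = e^(−Δt/τ) q[n−1] + G_i (τ/Δt)(1−e^(−Δt/τ)) Δε[n],
implemented as a first-order recursive filter; for sinusoidal drive the
residual discretisation error is O((ωΔt)²) ≈ 0.04% at 100 samples per
cycle.  Load noise is additive Gaussian with SD 0.01 N, the load-cell
resolution.  Sampling rates: 100 Hz for dynamic protocols (100× the 1 Hz
drive), 50 Hz for the quasi-static staircase (still 50× the 1 Hz
preconditioning, and the ~95-minute protocol stays cheap).

## Protocols

* Dynamic, 10% or 40% strain: 20 preconditioning cycles at 1 Hz, then
  5-cycle blocks at 0.1, 1 and 0.01 Hz (acquisition order; the analysis
  uses only the final period per block, so order does not affect
  estimates).  Amplitude = strain × nominal 5 mm height, i.e. ±0.5 mm and
  ±2.0 mm.  The strain denominator is the nominal height, not the 4.5 mm
  clamp gap — this is what makes ±0.5 mm equal 10% strain; the gap itself
  encodes a 10% compressive pre-strain.
* Static staircase: 5 preconditioning cycles at the step amplitude, 15 min
  rest, then 2.5% steps at 0.2 mm/s each held 20 min, to 10% net strain.
  The large-strain variant uses 10% steps held 5 min; with slow relaxation
  the shortened holds bias the modulus upward, a property the test suite
  asserts rather than hides.

## Estimators

* **Phase/moduli:** both channels are mean-removed (DC balance) and
  amplitude-normalised; δ is the phase difference of the fundamental FFT
  bins of the final commanded period, folded into [0, π/2).  Stress and
  strain amplitudes come from the same fundamental bins (robust to noise,
  consistent with the phase pipeline).  A window whose fundamental carries
  under 20% of non-DC channel power is rejected as unreliable, and
  large-strain windows (ε₀ > 0.15) are flagged `phase_reliable=False`
  since the response departs from a pure sinusoid.
* **Hysteresis:** cyclic shoelace area of the load–displacement loop,
  displacement in metres, reported in μJ; windows whose endpoints differ
  by more than 5% of the sweep are rejected as open loops.
* **Equilibrium stress:** trailing 10-s mean of the hold (and of the rest
  baseline); the window shrinks with a warning for shorter holds.  The
  modulus is the unconstrained OLS slope of equilibrium stress on strain;
  the intercept is reported as a diagnostic, not forced through zero.
* **Trilinear fit:** the branch is resampled onto a 601-point uniform
  displacement grid; Savitzky–Golay (order 3) smoothing and second
  derivative with a window of 10% of the grid.  5% windows leave the
  second derivative noise-dominated at 0.01 N load noise (breakpoint
  scatter ≈ 0.6 mm, frequent degenerate fits); 10% brings scatter to
  ~0.05 mm with noise-free recovery still exact, so 10% is the default and
  the window is a keyword argument.  Breakpoints are searched in the
  central 80% of the sweep; each zone's line fit excludes a one-window
  guard band around the breakpoints; a branch whose implied slope change
  is below 5% of the mean slope raises a degenerate-fit error (a straight
  line has no neutral zone).

## OCT pipeline

Images are cropped to the central 400×400 window (odd margins resolve
top-left; the pixel grid at 10.23 μm/px is authoritative, making the
window 4.09 mm).  The 21-plane feature stack comprises the original
image; DPAD at 1000 and 5000 iterations; z-scored 5×5, 15×15, 31×31,
100×3 and 3×100 medians; z-scored Haralick angular second moment, entropy
and sum of squares of the DPAD image (7×7 window, vertical co-occurrence
offset 1) and of the original (7×21 window, offsets 1 and 2); and the
z-scored speckle index (local SD/mean) in 5×5, 11×11, 101×3 and 3×101
windows.  Z-scores of constant planes are defined as 0.

Numerical choices: DPAD uses the Kuan-weight diffusivity
c = q₀²(1+q²)/(q²(1+q₀²)) clipped to [0,1], with q² the local 3×3 squared
coefficient of variation and q₀² its image-wide median (computed on a
stride-3 subsample each iteration), time step 0.2; grey levels are
quantised to 32 bins for the co-occurrence matrices; windowed Haralick
statistics are accumulated with box filters (one per observed grey pair),
and the sum-of-squares feature is the GLCM marginal variance, i.e. the
windowed variance of the quantised image.

The classifier is a 100-tree Random Forest evaluating 5 candidate
features per split, seeded, trained on labelled bright/dark masks
subsampled to 8000 pixels per image.  Boundary tracing replaces the
interactive initialisation of the production workflow: operator markers
(or, in tests, jittered ground-truth seeds) define a guide polyline, and
each column's border row is the subpixel 0.5-crossing of the smoothed
bright-class probability nearest the guide within a 10 px capture radius;
borders missing more than 5% of columns are rejected.  Thickness is
measured along the local normal of the upper border (tangent from a
σ=3 px smoothed gradient) to its intersection with the lower border, in
μm; only layers with both borders traced are included, and the overall
mean is the unweighted mean over all node measurements of all included
layers.

## Synthetic cohorts

The image generator draws band thicknesses from a truncated normal
(floor 2× pixel size), shares a sinusoidal undulation (default 15 μm
amplitude, 1.5 mm period) and optional tilt across boundaries, assigns
alternating bright/dark levels at contrast 0.5, and multiplies by gamma
speckle with unit mean and shape 4 (CV = 0.5, a strong but realistic
speckle level).  Ground truth (boundary polylines, per-layer perpendicular
thickness, bright/dark mask) survives cropping.  It does **not** emulate
depth-dependent attenuation, inter-lamellar matrix, fibre texture within
bands, or partially spanning lamellae — so recovery results demonstrate
correctness of the measurement geometry and the learning pipeline on
band-structured speckle, not performance on real OCT.

Cohorts couple lamellar thickness to shear moduli through a Gaussian
copula with latent correlation ρ (default −0.7; thicker lamellae ↔ lower
moduli), with both orientations sharing a modulus latent.  Group marginals
default to the published summary statistics: moduli 83.0±41.3 (radial)
and 226.2±81.9 kPa (circumferential) for control tissue, 23.7±22.1 and
52.2±36.8 kPa for degenerated tissue; mean lamellar thickness
324.67±26.76 μm versus 600.23±198.58 μm; group sizes 13 and 30.  Because
moduli must be positive the marginals are floor-truncated normals, which
shifts the realised control radial mean to ≈85 kPa (+2.5%) — accepted
rather than distorting the published SDs.  By default marginals are drawn
at mid-rank quantiles and permuted (`stratified=True`), pinning cohort
moments at their configured values so that cohort-level recovery error
reflects the estimators rather than small-n sampling luck; independent
draws are available with `stratified=False` and are used for the
statistical power and sign-recovery simulations, where sampling
variability is the point.

## Statistics

Shapiro–Wilk gates each comparison: all groups normal (p > 0.05) → Welch's
t-test between groups or repeated-measures ANOVA within; otherwise
Mann–Whitney U or Friedman.  Bonferroni adjustment is min(1, m·p) with the
family size declared by the caller (the analysis does not guess family
sizes).  Spearman correlations use tie-corrected ranks.  Samples are
treated as independent even when several discs come from one individual —
a documented simplification; no clustering correction is applied.

## Problem sizes and validation scales

Recovery experiments run at the study's sample sizes: 13 recordings per
orientation for the static pipeline, 4 training plus 10 test images per
thickness condition for the OCT pipeline (440 px generated, cropped to
400).  The static staircase is simulated at 50 Hz; the loss-tangent
recovery uses the full dynamic protocol at 100 Hz.  Noise-robustness
properties use 50–100 seeded replicates.  Feature computation is the
dominant cost (≈17 s per 400×400 image, almost entirely the 5000 DPAD
iterations).

## Known limitations

* Linear viscoelasticity only; no damage, poroelasticity or fibre
  reinforcement; 40%-strain simulations are *protocol* emulations, not
  tissue emulations.
* The boundary-refinement rule (column-wise probability-transition
  snapping) is an explicit stand-in for the interactive tracing tool used
  in production workflows.
* Synthetic speckle images are far more homogeneous than real OCT;
  classifier accuracies reported by the tests should not be read as
  expected field performance.
* Neutral-zone length is reported in mm with a strain-% convenience
  conversion.
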