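# Methods

## Model and geometry

All fitting stages share a one-dimensional synthesis–diffusion–clearance
model on a uniform cell-centered grid:

    ∂c/∂t = D ∂²c/∂x² + p(x) − k c

with intensity in arbitrary fluorescence units, distance in µm and time in
s. One dimension is the canonical effective geometry for bleach-recovery
fitting in embryonic tissue at the field's working scale; the full 3-D
embryo geometry (curved blastoderm, interstitial tortuosity) is not
modeled, and the fitted D is therefore an *effective* tissue-scale
diffusivity. The exact fit geometry used by the original confocal FRAP
toolchain is not publicly specified; the 1-D form here is a declared
stand-in, and quantitative equivalence with that toolchain is not claimed —
what the tests establish is correct parameter recovery on this package's
own forward model.

The solver uses Crank–Nicolson time stepping (unconditionally stable,
second order), with output intervals subdivided so the diffusion number
D·Δt/Δx² stays at or below `max_step_number` (default 1) for accuracy, and
k·Δt ≤ 0.1. A forward-Euler variant exists and rejects steps violating
D·Δt/Δx² ≤ 1/2. Boundaries are zero-flux by default (reflecting ghost
cells), with an absorbing (zero-value wall) alternative and an optional
clamped-concentration source cell; the Dirichlet row is built into the
implicit matrix so the fixed point is exact for any step size. With p = k =
0 and zero-flux walls the scheme conserves mass to round-off; halving both
grid spacing and step changes solutions by well under 1%.

Closed forms used as oracles: the steady-state exponential
c₀·exp(−x·√(k/D)) (compared on x ≲ 2.5 λ of a 500 µm domain, where the
finite-wall cosh correction is below 1%), the heat kernel for a point
release, and uniform-field exponential decay.

## FRAP

A pre-bleach steady state is computed from the parameters (uniform p/k for
whole-domain production, numerically relaxed for a restricted source); the
bleach multiplies the field inside the bleach interval by (1 −
bleach_depth) instantaneously, and the first post-bleach frame defines
t = 0. The fit minimizes squared residuals between the measured and
simulated ROI means over any subset of {D, p, k} (D always free).
Parameters are optimized in log-space — they are positive scale parameters
spanning orders of magnitude, and the log transform conditions the
otherwise flat p/k directions — inside bounds D ∈ [10⁻³, 100] µm²/s,
k ∈ [0, 10⁻²] /s, p ≥ 0, with a 3-start seeded multi-start and ties broken
by lowest SSR then lowest D.

The four recorded exclusion criteria are operationalized as:

* `low_r_squared` — overall R² < 0.8;
* `high_local_variability` — median absolute successive-residual difference
  exceeding 3× the global residual MAD;
* `linear_increase` — a straight-line fit within 0.01 R² of the model fit,
  positive slope, and a model-predicted plateau not approached within the
  record (more than 10% of the initial recovery gap still open at the last
  frame, judged on the model prediction so an unconverged fit cannot mask
  it);
* `early_kinetics_mismatch` — mean relative residual over the first 10% of
  frames exceeding 3× that over the remainder.

Optimizer failure is reported as a `degenerate` QC failure, not an
exception. The thresholds are reproducible surrogates for qualitative
visual-inspection criteria; they were chosen for separability on the
synthetic forward model (noiseless self-fits reach R² > 0.999 and pass; a
pure-noise or strictly linear record fails with the expected reason) and
are configurable only in code, deliberately, to keep QC verdicts
deterministic.

## FDAP

Converted-pool decay is fit with c(t) = c₀·e^(−kt) + offset on retained
frames. Whether the original analysis included an offset/plateau term is
not stated in the methods it derives from; the offset is included by
default (background fluorescence exists in real recordings and the
synthetic truth carries it) with a no-offset flag. The nonlinear fit is
seeded from a log-linear regression on the intensity excess over its
floor; k is bounded in [0, 0.1] /s. R² < 0.88 fails QC, and a flat series
returns a degenerate fit with k = 0.

Frame exclusion tags frames at/above the saturation level, patches them by
interpolation, then flags artifact frames whose *relative* residual from a
local neighbor median (window of 5 excluding the center, with
linear-extrapolation padding at the ends) exceeds `artifact_z` (default 5)
robust SDs. Relative residuals are used because fluorescence noise scales
with signal; a 5% relative floor prevents smooth-curvature residuals on
near-noiseless records from being mistaken for artifacts. The detection is
two-pass: gross spikes are patched out before the final verdict so they do
not pollute their neighbors' baselines.

## Gradient profiles and the normalization model

Profiles are distance-binned means from the source edge (images oriented
upstream so the source is the left border), with masked pixels excluded —
never zeroed — and empty bins carrying NaN. Background (the per-bin median
of uninjected-control profiles) is subtracted without clipping, so
intensities may go negative; clipping would bias the bin means.

The inter-embryo normalization model I_n(x) = A_n·c̄(x) + b_n is fit per
embryo by ordinary least squares against the regressor c̄(x), the pointwise
mean of all input profiles on a common grid (linear interpolation onto the
coarsest input grid; bins beyond an embryo's extent are missing and drop
out of the per-bin mean). c̄ is computed once from the raw
background-subtracted profiles, matching the described single-pass
procedure; an iterative refinement (recompute c̄ from normalized profiles)
is available but off by default. (A_n, b_n) are identifiable only up to the
affine gauge of c̄ — with noiseless truth I_n = a_n·g + c_n the exact
solution is A_n = a_n/ā and b_n = c_n − A_n·c̄₀ — so tests assert gauge
ratios, not absolute values. A constant c̄ makes A_n unidentifiable and is
signaled per embryo.

"Mean thresholding" for the source mask is implemented as the iterative
intermeans (isodata) threshold, the standard analog of the Fiji "Mean"
auto-threshold family. Punctum detection uses h-maxima morphological
reconstruction (prominence ≥ `min_prominence`), rejects non-compact
plateau/ridge maxima (area above π·min_separation² px — the crest of the
smooth gradient itself is not a punctum), and enforces pairwise separation
brightest-first.

Clone-edge profiles threshold the far-red tracer at a configurable
intensity (default 700, an instrument-specific value in arbitrary units),
keep the largest connected component, and average ligand intensity in
angular sectors laid out radially around the clone; the sector count tiles
the full circle with arc width ≈ `roi_width_um` (default 70 µm) at the
clone edge radius, so on a radially symmetric field the profile is
insensitive to the ROI width. The control median is subtracted and the
profile normalized to its value at distance 0 from the edge.

## Nuclear quantification

Nuclear masks are Otsu thresholds of the DAPI projection with a size
filter; pSmad intensities are read only under this mask. Positivity uses a
single declared threshold per run, defaulting to background median + 3×
background MAD from non-nuclear pixels (no standard numeric rule exists;
this robust rule is configurable). Tier binning is straight (distance from
the margin divided by the nuclear diameter, default 8 µm, 1-based); a
curved-margin geometry is not modeled. The tier count is the largest T
with every tier 1..T containing a positive nucleus — the contiguity rule
implementing "maximum number of positive tiers from the margin" — with a
highest-occupied-tier mode behind a flag.

Transplanted-cell counting is scale-matched Laplacian-of-Gaussian
detection (σ = radius/√3 per axis, clamped to ≥ 0.8 voxel so a coarse
z-step does not amplify voxel noise) followed by a quality threshold on
the LoG response; interactive curation is modeled as an explicit numeric
threshold plus an exclusion-coordinate list, keeping the operation
deterministic. Transplant profiles are rectangular ROIs (default 100 µm
height) from the transplant edge, background-subtracted and divided
exactly by the transplanted-cell count.

## Statistics

t tests (pooled df = n₁+n₂−2, or Welch–Satterthwaite), the two-tailed
variance-ratio F test (doubling the smaller tail, as in R's `var.test`;
whether the original F tests were one- or two-tailed is not stated —
two-tailed is chosen and flagged here), and Shapiro–Wilk delegate to
scipy. The Wilcoxon rank-sum statistic is computed in-package with
midranks, the tie-corrected null variance

    var(W) = n₁n₂/12 · [(N+1) − Σ(t³−t)/(N(N−1))]

and a continuity-corrected two-tailed normal p — the appropriate procedure
when ties preclude the exact distribution. Against exhaustive enumeration
(all group sizes 3–8, all achievable statistics, no ties) the
approximation stays within 0.02 absolute p for groups of ≥ 5 per side and
within 0.04 for the smallest groups; the continuity-corrected rule's exact
type-I level at n=8 per group and α=0.05 is 0.0379.

Cohen's d uses the pooled SD and the Hedges small-sample correction
J = 1 − 3/(4N − 9) (the convention of the commonly used effect-size
calculators; the exact gamma-function form is available behind a flag).
The sign convention is condition − reference throughout, so a treatment
that lowers the measurement yields d < 0.

## Synthetic data

The generators emulate the statistical structure each stage assumes, at
the measured study conditions: effective diffusivity ~2 µm²/s for the
wild-type ligand (1 µm²/s with co-receptor overexpression, >3 µm²/s
without Type-I receptors, 40 µm²/s free), gradient length scale 100 µm,
extracellular clearance 10⁻⁴ /s (half-life ≈ 2 h, a realistic
representative value for secreted TGF-β-family ligands at this stage; no
measured clearance constant is asserted),
nuclear diameter 8 µm on a jittered hexagonal lattice, and 12 positive
tiers for the wild-type signaling range. FRAP frame schedules span ~3 ROI
recovery times (w²·3/8D over a 40 µm bleach window, 60 frames) so each
condition is sampled on its own timescale.

Fluorescence noise is multiplicative Gaussian (relative sd, default 1% for
FRAP series, 2% for FDAP and image channels), matching the high-intensity
light-sheet regime; a Poisson mode is available for image channels. What
the generators do *not* emulate: optical point-spread functions,
acquisition photobleaching, embryo curvature and outline segmentation,
depth-dependent attenuation, intracellular/extracellular compartment
mixing, and biological inter-embryo variability beyond the amplitude and
background terms of the normalization model. Passing tests therefore
demonstrate correctness of the quantification chain on data with the
assumed structure — not robustness to every real-data pathology.

Every generator is a pure function of (parameters, seed); master seeds fan
out to stages via `numpy.random.SeedSequence(master, spawn_key=(stage,))`
so adding a stage never perturbs earlier stages' draws.

## Problem sizes and numerical defaults

Default scenes are 200×300 px at 2 µm/px (a 400×600 µm field, ~1900
nuclei); FRAP domains are 200 µm at Δx = 2 µm with a 40 µm bleach window
and 60 frames; recovery studies use 5–20 records per condition and FDAP
studies 50 series; the null-calibration study uses 2000 simulations at
n = 8 per group. These sizes were chosen so each recovery target is
measured with comfortable statistical margin while the full suite stays
desk-scale. Tolerances: optimizer xtol 10⁻¹⁰ (FRAP, log-space) and 10⁻¹²
(FDAP); fits are bit-reproducible for identical inputs and options.

## Known limitations

* The FRAP model is 1-D with an idealized instantaneous bleach; immobile
  fractions, acquisition bleaching and 3-D PSF effects are out of scope.
* Measurements that require the original embryo imaging data (specific
  clearance constants, real-data effect sizes) cannot be recomputed here;
  the recovery surface is parameter estimation at the reference
  diffusivities plus the property suites.
* The Wilcoxon normal approximation is intrinsically coarser than 0.02
  absolute p for groups smaller than 5 (worst 0.0375 at 3 vs 3), a
  property of the approximation, not of this implementation.
* Tier counting assumes straight tier bins parallel to the margin and a
  single positivity threshold per run.
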