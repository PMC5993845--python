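# Methods

This note documents the models, the simulator, the numerical choices, and
the limits of what the test suite demonstrates.

## Southampton SBR estimator

The specific binding ratio of one hemisphere is

    SBR = (C_StrVOI − C_bg/vox · N_StrVOI) / (C_bg/vox · V_str),

with `V_str` = 11.2 mL converted to voxels of the grid. The estimator's
defining property — adding pure-background voxels to the striatal VOI does
not change the value — holds exactly in infinite, uniform background; the
implementation is therefore built around three guarded steps:

- **Peak localization.** The volume is smoothed (Gaussian, 8 mm FWHM
  default) to stabilize the argmax under counting noise; the midline is
  the sagittal plane through the smoothed center of mass and one peak is
  taken per half. A peak must exceed 1.2× the median intensity of the
  "body" (voxels above 5% of the peak, which excludes the blurred air
  halo); a uniform volume raises a degenerate-peak error, a one-sided
  volume a lateralization error. For simulated phantom acquisitions the
  ground-truth compartment centers are carried in volume metadata and used
  directly (`quantify_phantom`) — in a physical phantom session the
  compartment positions are likewise known — which keeps the uniform
  (null-binding) fill quantifiable.
- **Striatal VOI.** A fixed-physical-size axis-aligned box: the nominal
  striatum bounding box (half-extents 10 × 22 × 12.2 mm) dilated by a
  margin (default 20 mm ≈ 4 σ of a 12 mm FWHM PSF, capturing >99.9% of
  blurred striatal counts). The exact VOI geometry of licensed clinical
  implementations is unpublished; a box is legitimate precisely because
  the estimator is VOI-shape-insensitive. Box size never depends on image
  intensities; clipping at the grid edge beyond 5% of the nominal volume
  is recorded in provenance. Margins larger than ~30 mm eventually reach
  the contralateral striatum and air outside the head, both of which break
  the background-invariance; the tests exercise this boundary.
- **Reference region.** Brain voxels within a 44 mm axial slab centered on
  the highest striatal activity, minus both striatal VOIs. The brain mask
  thresholds at 15% of the slab's 99th-percentile intensity, with two
  robustness measures found necessary on simulated data: the percentile is
  computed on a smoothed copy of the volume (raw Poisson counts punch
  speckle holes into the mask, and the subsequent distance-based erosion
  would carve around every hole) and outside the striatal VOIs (a hot
  striatum otherwise drags the 99th percentile so high that the whole
  background falls below threshold). The mask is then eroded by 22 mm
  (Euclidean distance, computed on the full volume so the slab faces are
  not treated as edges). The erosion strips the partial-intensity shell
  the PSF smears across the head boundary; without it the reference mean
  sits ~1% low and, amplified by the oversized VOI (N_StrVOI ≈ 30 ×
  V_str), the SBR reads up to ~0.4 too high at 12 mm FWHM. 22 mm clears
  ~3 σ of a 12 mm FWHM blur plus the mask-smoothing halo.

Negative SBRs are returned unclamped (flagged), so calibration operates on
the full linear scale. Whether 11.2 mL is per hemisphere or total in
clinical software is ambiguous; it is implemented per hemisphere with a
`vol_str_ml` override for sensitivity analyses (SBR scales exactly
inversely with it). The reference region uses all non-striatal brain
voxels in the slab rather than a cortex-specific mask.

## Digital phantom

Two mirrored ellipsoidal striatal compartments (semi-axis proportions
10 : 22 : 12.15, scaled to enclose exactly 11.2 mL each, centers ±25 mm
from midline, 10 mm anterior) inside an ellipsoidal head background
(semi-axes 80 × 95 × 70 mm). Rasterization ranks voxel centers by
normalized ellipsoidal radius and keeps the smallest k so that the
digitized compartment volume is within half a voxel of 11.2 mL — the
region stays an ellipsoid level set while the volume error stays ≤0.4% at
the coarsest clinical voxel (3.4 mm). Ground truth: SBR = concentration
ratio − 1 per hemisphere, the relation that physical aliquot measurements
in a well counter establish. The `filling_sequence` helper mirrors the
three-fill protocol: uniform (~5 kBq/mL), striata refilled to 8:1/4:1
(~40/~20 kBq/mL), background raised 33% giving ~6:1/~3:1.

## Scanner and reconstruction emulation

Physical projection/reconstruction (FBP, OSEM, Chang/CT attenuation
correction, energy-window scatter correction, collimator response) is out
of scope. Its net effect on SBR is emulated per reconstruction condition
as an affine transform of the specific/background contrast — justified by
the observed near-perfect linearity of measured-vs-true phantom SBR that
calibration itself relies on — applied in the ideal pre-blur domain,
followed by Gaussian PSF blur and Poisson noise scaled to an expected
total count (3×10⁶ default):

- gain `a` multiplies the per-voxel contrast `(v − bg)/bg`;
- offset `b` adds `b · bg · V_str` specific counts per hemisphere, spread
  over that hemisphere's compartment, so the measured-SBR relation is
  `a·s + b` by construction;
- an optional quadratic term `c·u²` models the residual excess of
  scatter-corrected conditions that a *linear* calibration cannot remove
  (phenomenology of high-energy septal penetration, not its physics).

Default biases order the five conditions as raw SBR means
ChangACSC > CTACSC > ChangACNOSC > CTACNOSC > NOACNOSC (gains 0.71–1.05,
offsets 0–1.2, quad 0.02 under scatter correction). These are simulator
choices reproducing the qualitative condition ordering, not measured
system constants — actual per-scanner calibration equations are always
user inputs or simulator products, never hard-coded.

## Synthetic cohort

Study conditions emulated by default: n = 510 scans; age ~ Uniform(30, 83)
years; 55% women; scan start ~ Normal(3.5 h, 0.5 h) truncated at 0.5 h
(spanning the two serial scan-start times of a dual-scan protocol).
Average SBR = 10.610 − 0.063·age + 0.263·start + 0.461·1[female] +
Normal(0, 1.38). The residual SD 1.38 is chosen so the large-n 95%
prediction half-width is 1.96 × 1.38 ≈ 2.70, the constant gap between the
decade means and their lower prediction limits in the published normative
table. The left/right split draws a signed asymmetry d ~
Normal(max(AI model, 0), 3.7) in AI units and sets R = m(1 + d/200),
L = m(1 − d/200); the positive mean gives the right-dominance seen in
paired testing, and with zero asymmetry noise the recorded AI equals the
AI-model prediction exactly. The AI noise SD 3.7 is back-calculated from
the weak pooled AI-age correlation (r ≈ 0.12 with slope 0.029/year over a
15.3-year age SD). Folding |d| inflates the mean AI somewhat above the
model line when the noise is on; AI parameter-recovery statements
therefore hold exactly only in the noise-free case. Sex is coded
female = 1 internally and "F"/"M" in files. Each scan is an independent
record with its own subject id; within-subject correlation of serial
scans is not modeled (the 510-scan analyses treat scans as independent
records too).

What the generator does *not* emulate: anatomical variability (one fixed
phantom geometry), striatal atrophy with age, subject motion,
center-specific acquisition quirks beyond the affine bias, and the
529 keV septal-penetration physics (only its quadratic phenomenology).
Passing tests therefore demonstrate the *pipeline's* correctness and the
statistical machinery's calibration under the stated generative model,
not clinical accuracy on real scans.

## Calibration

One curve per (scanner, condition): OLS of measured (Y) on true (X) SBR,
matching the orientation of calibration plots; harmonization applies the
inverse (measured − b)/a. The alternative orientation (regress true on
measured, apply forward) is available behind a config switch. Both
hemispheres of each fill contribute points, and left and right SBRs are
calibrated with the same curve. Quality gates reject slope ≤ 0.1 or
|r| < 0.9 — phantom fits are near-perfectly linear, so poor fits signal
acquisition problems rather than statistics.

## Normative statistics

- **Simple regression** is closed-form (normal equations), carrying
  x-mean and Sxx so t-based CI/PI evaluate at any x:
  half-width = t · s · sqrt([1 +] 1/n + (x − x̄)²/Sxx).
- **Multiple regression** (average SBR or AI on age, start time, female
  indicator) uses statsmodels OLS; the model stores (X'X)⁻¹ for exact
  t-based prediction intervals at arbitrary covariates. The tabulated
  constant PI half-width (2.70) emerges at large n; it is never
  hard-coded.
- **Decade summary** bins [30–39] … [80–89]. Default mode reports the
  per-group age-regression value at the decade midpoint (lo + 4.5) — the
  published decade means are exactly linear across decades, indicating
  they are regression-predicted values, and this mode reproduces that
  behaviour; `mode="raw"` gives raw group means. PI limits always come
  from the per-group regression at the midpoint.
- **ICC** defaults to ICC(2,1) (two-way random, absolute agreement,
  single measure — the form that penalizes systematic offsets between
  reconstruction conditions), with ICC(3,1) available; confidence
  intervals use the standard F-distribution construction
  (Satterthwaite-type df for the agreement form) and are cross-checked
  against pingouin in the tests.
- **ANOVA** is Type III with effects sex, age, sex × age, start time; age
  and start time continuous. p-values below 1e−15 are reported as
  "< 1e-15" in formatted output, never as zero.
- **z-scoring** of a new subject is (observed − expected)/residual SD,
  flagged when the observation falls below the 95% lower prediction
  limit. On the published decade table the flag threshold corresponds to
  a ~35% reduction from the 60–69 decade mean.

## Published reference values

`datnorm.published` bundles the printed normative results of the 510-scan
multicenter healthy-control database (regression coefficients, per-sex
age lines, decade table, per-condition summaries with ICCs). They serve
as the cohort generator's default parameters and as inputs to the
arithmetic consistency checks (e.g. women exceed men by 12.2% at 30–39;
decline per decade 6.3%/5.3%/7.5% for both/men/women; the calibrated
uncorrected grand mean 8.16 sits 12% below scatter-corrected Chang). The
original-scale uncorrected-vs-ChangACSC gap computes to ~45% from the
printed grand means; the abstract-style figure of 46% presumably reflects
a per-scan mean of ratios, so both aggregations are exposed and neither
is asserted.

## Problem sizes and determinism

Simulations are sized for fast, repeatable runs: phantom grids at
2.2–3.4 mm voxels (~0.5 M voxels), phantom series of three fills, demo
cohorts of 510–600 scans, parameter-recovery cohorts of 5000, interval
coverage at 10 000 new draws, ICC-improvement checks over 200 replicate
cohorts at the SBR level, and ANOVA null calibration over 400 replicates
of n = 150. Every stochastic component takes a NumPy `default_rng` seed;
series and pipeline stages derive child seeds via `SeedSequence.spawn`,
and reruns of the same configuration are bit-identical for deterministic
artifacts. Pipeline artifacts carry sidecar provenance (seed, config
hash, package version).

## Known limitations

Caudate/putamen subfield SBRs, MRI-guided VOIs, partial-volume
correction, handedness effects, longitudinal within-subject modeling and
nonlinear age models are out of scope. The digital phantom's geometry is
generic (the physical product's exact striatal shape and head dimensions
are not public). DICOM and vendor formats are not read; volumes are
NIfTI-1, tables CSV, models JSON, configuration YAML/JSON.
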