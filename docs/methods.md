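# Methods

This note documents the models, conventions and numerical choices behind
`adcradiomics`, and what the synthetic data can and cannot show.

## ADC mapping

The two-point mono-exponential model assumes pure Gaussian diffusion:
S_b = S₀·exp(−b·ADC). With b = 0 and 800 s/mm² the voxelwise estimate is
ADC = ln(S₀/S_b)/Δb, reported in 10⁻⁶ mm²/s. Voxels with a nonpositive
signal at either b-value are marked invalid and stored as NaN — the
least-surprise convention, since no log-ratio exists there. Negative ADC
estimates (S_b > S₀, magnitude noise) are *retained*, not clipped, so
downstream statistics see the data as measured; their count is reported on
the map. The model ignores perfusion (IVIM) and non-Gaussian diffusion;
including b = 0 therefore biases ADC slightly upward in perfused tissue.
Multi-b or bi-exponential fitting is out of scope.

## VOI, morphology

The VOI is the stack of per-slice binary ROIs; gaps (empty slices inside the
stack) are allowed. Area is the summed true-voxel count × in-plane voxel
area over all slices. Volume extrudes each slice's area over one slice
interval (slice thickness + gap, default 5 mm = 4 + 1). Maximal tumour
diameter (MTD) is computed per slice, as the largest Euclidean distance
between in-plane voxel *centres*, maximised over slices — the clinical
caliper convention for ROIs drawn slice by slice; no half-voxel edge
compensation is added, so a 10-voxel row at 1 mm spacing has MTD 9 mm. A
3-D diameter is available behind `mtd_mode="3d"`.

## Histogram features

Percentiles use linear interpolation (the numpy default); dialects differ
across ecosystems, so this is fixed and tested. Skewness is the biased
moment coefficient g₁. Kurtosis defaults to the non-excess (Pearson)
convention, under which a normal distribution scores 3; published kurtosis
values near 12 are consistent with either convention on heavy-tailed lesion
histograms, so a flag switches to excess. A constant sample gets skewness
and kurtosis 0 by convention. Entropy is −Σ pᵢ log₂ pᵢ over an equal-width
histogram with 128 bins (default) spanning the lesion's own min–max range;
because binning and log base are free choices, absolute entropy values are
comparable only within a fixed configuration, and no attempt is made to
reproduce published absolute entropies.

## GLCM texture

Co-occurrence is accumulated in 2-D per slice and summed over the VOI:
a four-angle (0/45/90/135°) scheme is inherently 2-D, and DWI slices are
thick (≈5 mm) relative to the ≈1.5 mm in-plane resolution, so through-plane
neighbours are not texture at the same scale. Default configuration:
64 equal-width gray levels over the lesion's ADC range, distance 1,
symmetric accumulation, probability normalization; all selectable,
including a fixed-bin-width (absolute-scale) quantization. Features are
computed per direction and averaged (`direction_average="features"`);
averaging the matrices first is available, and the two agree for features
linear in P (autocorrelation).

In the correlation formula, μ and σ² default to the mean and variance of the
marginal gray-level distribution, which bounds correlation in [−1, 1]; an
"element" dialect (moments of the matrix entries themselves) is provided
because the formula's symbols are ambiguous in parts of the literature. When
only one gray level is occupied, σ = 0 and correlation is reported as 0 with
a degeneracy flag. Directions with no co-occurring voxel pair (possible for
thin lesions) are excluded from the average with a warning.

Published absolute texture magnitudes from in-house software (correlation of
order 10, homogeneity of order 10³–10⁴) imply an unnormalized or rescaled
matrix whose exact convention is not recoverable; this package's contract is
formula correctness against exhaustive-enumeration oracles, not reproduction
of those absolute values. Directional *effects* (e.g. lower autocorrelation
in more heterogeneous lesions) are reproduced and tested.

## Change rates

Morphological response keeps its sign, (pre − mid)/pre × 100, so shrinkage
is positive; ADC-feature response is sign-blind, |mid − pre|/pre × 100.
Patients missing a timepoint are excluded with a logged count (no
imputation).

## Statistics

Group comparison routes by Shapiro–Wilk at α = 0.05 per group: both normal →
Welch t-test (unequal variances assumed — safer than the pooled test when
group sizes are 26 vs 10), otherwise two-sided Mann–Whitney U. A
zero-variance group routes to Mann–Whitney with a flag.

The empirical AUC is the tie-corrected Mann–Whitney statistic U/(n₁n₂),
auto-oriented to ≥ 0.5 with the orientation recorded (for ADC features, low
values predict recurrence). The 95% CI uses DeLong's structural-components
variance (Hanley–McNeil available). The operating cutoff maximises the
Youden index over midpoints between adjacent distinct scores; accuracy is
the pooled correct fraction, which reproduces published accuracy arithmetic
such as (18/26 + 9/10)/36 = 75.0 %.

The Dunn–Šidák level 1 − (1 − α)^(1/m) is applied per timepoint per feature
family (m = 10 histogram, m = 4 texture), matching the table structure of
such studies. Stepwise logistic regression is forward with likelihood-ratio
entry (p-enter 0.05) and backward removal (p-remove 0.10), on internally
standardized features; under (quasi-)separation — likely with n = 36 and
strong effects — a small ridge (λ = 10⁻³) stabilises the fit and the result
carries a separation flag, with Wald p-values from the penalized Hessian.
Contingency comparisons use chi-square with continuity correction, switching
to Fisher's exact test when an expected cell is below 5. Inter-observer
agreement is ICC(2,1) — two-way random effects, absolute agreement, single
measure (computed via pingouin), the standard choice for two human observers
rating all cases — with its F-based 95% CI.

## Synthetic data

**Feature-level cohorts** draw each feature independently per group:
normal for morphology/histogram features (published as mean ± SD), lognormal
for texture features (published as median (IQR), right-skewed). The
lognormal is parameterized by the printed median and IQR ratio
(σ_log = ln(q₃/q₁)/(2·0.6745)); printed quartiles are not exactly
log-symmetric, so individual quartiles are matched approximately, the median
and IQR ratio exactly. Within-patient correlations are not published, so
independence is an explicit simplification: multivariate statements (e.g.
which feature stepwise selection keeps) are only qualitatively meaningful on
these cohorts.

**Phantoms** place an ellipsoidal lesion (default semi-axes 16/13/11 mm) in
a 64×64×10 volume at 1.5×1.5×5 mm. The solid compartment is a Gaussian
random field (mean 950, SD 120 ×10⁻⁶ mm²/s, correlation length 2 voxels);
necrotic foci are thresholded smoothed noise covering fraction f of the
lesion (default 0.15) at mean 2200 ± 150 — blobs rather than spheres so the
GLCM sees realistic spatial correlation. Signals follow the mono-exponential
model with Rician noise (σ = 8 on S₀ = 1000 by default), applied to the
magnitude signals rather than to ADC, since that is where magnitude-MR noise
arises. Observer 2's mask is a one-voxel dilation or erosion (seeded choice)
of the true mask.

The two-arm study conditions encode the biology reported for
recurrence: the recurrence-like arm is mostly solid (f = 0.05, solid ADC
930, correlation length 1.2 voxels — more heterogeneous), the
nonrecurrence-like arm necrotic and smoother (f = 0.30, solid ADC 1000,
length 2.5). Mid-treatment phantoms raise the solid-compartment ADC by
270 (nonrecurrence) / 190 (recurrence) ×10⁻⁶ mm²/s and shrink lesions by
15 %, mirroring the published group-mean ADC rise under therapy. Phantoms
emulate lesion composition and observer variability; they do not emulate
pelvic anatomy, distortion, motion, or scanner-to-scanner variation, so
passing tests demonstrate correctness of the measurement chain, not clinical
performance on real DWI.

## Problem sizes and determinism

The demo pipeline uses 8 + 6 patients, two timepoints and two observers
(≈5 s); the binormal AUC reproduction uses 2000 replicates per feature
(≈2 s each); these sizes were chosen so the whole validation chain runs
comfortably on a laptop while keeping Monte-Carlo error well inside the
tolerances tested. All randomness flows through `numpy.random.Generator`
seeds; a fixed seed makes every output table byte-identical across reruns,
and the run manifest records the seed and a configuration hash.

## Known limitations

* Two-point ADC only; no IVIM/kurtosis fitting, no registration between
  timepoints.
* GLCM conventions (quantization, normalization, σ dialect) follow explicit
  defaults rather than any vendor software; absolute texture magnitudes are
  configuration-dependent.
* Feature-level cohorts assume independent features; phantom cohorts induce
  correlations mechanistically but from a two-compartment model only.
* The stepwise procedure with n ≈ 36 and separation-prone effects yields
  unstable Wald p-values; the separation flag should be heeded.
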