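# adcradiomics

Whole-lesion ADC histogram and GLCM texture analysis for two-b-value
diffusion-weighted MRI (DWI), with the cohort statistics used in
recurrence-prediction studies and a synthetic cohort/phantom generator so the
entire pipeline runs and can be validated without patient data.

The package is aimed at quantitative-imaging researchers who want to test
whether whole-tumour apparent diffusion coefficient (ADC) features — measured
before and during concurrent chemo-radiotherapy (CCRT) — predict treatment
outcome, for example in advanced cervical cancer.

## What it computes

**ADC mapping.** From paired DWI volumes at b = 0 and b = 800 s/mm², the
mono-exponential model gives per voxel

    ADC = ln(S₀ / S_b) / (b_high − b_low),    reported in 10⁻⁶ mm²/s.

**Whole-lesion features.** Per-slice ROIs are stacked into a volume of
interest (VOI) and summarised by

* morphology: maximal tumour diameter (largest in-plane distance between
  voxel centres), total ROI area, volume (area × slice spacing);
* first-order histogram: ADC mean, the 5/10/25/50/75/90th percentiles
  (linear interpolation), skewness (g₁), kurtosis (Pearson, normal → 3),
  and histogram entropy −Σ pᵢ log₂ pᵢ;
* GLCM texture: gray-level co-occurrence matrices P(i, j) at distance 1 in
  the four in-plane directions 0°/45°/90°/135°, accumulated over all slices,
  from which

      correlation     = Σᵢⱼ (i−μ)(j−μ) P(i,j) / σ²
      autocorrelation = Σᵢⱼ i·j·P(i,j)
      entropy(H)      = −Σᵢⱼ P(i,j) log₂ P(i,j)
      homogeneity     = Σᵢⱼ P(i,j) / (1 + (i−j)²)

  evaluated per direction and averaged. Higher autocorrelation and
  homogeneity indicate a *less* heterogeneous lesion.

**Longitudinal change.** Signed morphological response
(pre − mid)/pre × 100 % and sign-blind ADC response |mid − pre|/pre × 100 %.

**Cohort statistics.** Shapiro–Wilk-routed group comparison (Welch t /
Mann–Whitney U), empirical ROC with DeLong 95% CIs and Youden-optimal
cutoffs, Dunn–Šidák familywise correction, forward stepwise logistic
regression with likelihood-ratio entry tests, contingency-rate comparison,
and inter-observer ICC(2,1).

**Synthetic data.** Feature-level cohorts drawn from published per-group
summary statistics (26 nonrecurrence / 10 recurrence), and image-level DWI
phantoms: ellipsoidal lesions with a smooth low-ADC solid compartment,
optional high-ADC necrotic foci, Rician signal noise, and a morphologically
perturbed second-observer mask, with full ground truth.

## Worked example

```python
from adcradiomics import PhantomSpec, compute_adc, histogram_features, simulate_phantom

for f in (0.0, 0.3):   # necrotic volume fraction
    spec = PhantomSpec(necrotic_fraction=f, rician_sigma=0.0, observer_perturb_vox=0)
    phantom = simulate_phantom(spec, rng=1)
    h = histogram_features(compute_adc(phantom.study), phantom.mask_obs1)
    print(f, round(h.p50, 1), round(h.p75, 1), round(h.p90, 1))
```

prints

```
0.0 956.9 1018.7 1070.3
0.3 995.8 2007.9 2308.3
```

With 30 % necrosis the 75th/90th percentiles jump into the necrotic ADC range
(~2200 × 10⁻⁶ mm²/s) while the median barely moves: the upper histogram tail
encodes tissue composition, which is why the 75th/90th percentiles carry
prognostic information that the mean alone misses. The `examples/` directory
walks through each capability (ADC mapping, lesion features, texture, cohort
statistics, the full pipeline); `adcradiomics run --seed 11 --out-dir demo`
runs the complete synthetic study from the shell.

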