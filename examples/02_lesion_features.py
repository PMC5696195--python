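"""Whole-lesion morphology and ADC histogram features.

Simulates a lesion with a necrotic (high-ADC) compartment and shows how the
upper percentiles of the whole-lesion ADC histogram respond to necrosis while
the median barely moves — the reason 75th/90th percentiles carry prognostic
information that the mean alone misses.
"""

from adcradiomics import PhantomSpec, compute_adc, histogram_features, morphology, simulate_phantom

for f in (0.0, 0.3):
    spec = PhantomSpec(necrotic_fraction=f, rician_sigma=0.0, observer_perturb_vox=0)
    phantom = simulate_phantom(spec, rng=1)
    adc_map = compute_adc(phantom.study)

    morph = morphology(phantom.mask_obs1)
    hist = histogram_features(adc_map, phantom.mask_obs1)

    print(f"--- necrotic fraction {f:.0%} ---")
    print(f"  MTD {morph.mtd:.1f} mm | area {morph.area:.0f} mm^2 | volume {morph.volume:.0f} mm^3")
    print(
        f"  ADC mean {hist.adc_mean:7.1f} | p50 {hist.p50:7.1f} | p75 {hist.p75:7.1f} | "
        f"p90 {hist.p90:7.1f} (x 1e-6 mm^2/s)"
    )
    print(f"  skewness {hist.skewness:5.2f} | kurtosis {hist.kurtosis:5.2f} | entropy {hist.entropy:4.2f} bits")

# With 30% necrosis, p90 jumps into the necrotic ADC range (~2200) while the
# median stays near the solid compartment (~950): the histogram tail encodes
# the tissue composition.
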