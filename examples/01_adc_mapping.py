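"""Compute an ADC map from a simulated two-b-value DWI study.

Builds a small phantom with a lesion of known diffusivity, fits the
mono-exponential model voxel-wise, and compares the recovered lesion ADC
against the generator's ground truth.
"""

import numpy as np

from adcradiomics import PhantomSpec, compute_adc, simulate_phantom

spec = PhantomSpec(solid_adc_mean=950.0, necrotic_fraction=0.0, rician_sigma=5.0)
phantom = simulate_phantom(spec, rng=0)

adc_map = compute_adc(phantom.study)
lesion = phantom.mask_obs1.mask

print(f"volume shape:              {adc_map.shape}")
print(f"valid voxels:              {adc_map.valid_mask.mean() * 100:.1f} %")
print(f"negative-ADC voxels:       {adc_map.n_negative} (noise-driven, retained)")
print(f"lesion ADC, recovered:     {adc_map.adc[lesion].mean():8.1f} x 1e-6 mm^2/s")
print(f"lesion ADC, ground truth:  {phantom.truth['lesion_adc_mean']:8.1f} x 1e-6 mm^2/s")

# The recovered mean sits within the Rician-noise tolerance of the true field;
# background tissue (~1600) and lesion (~950) are clearly separated.
print(f"background ADC (median):   {np.median(adc_map.adc[~lesion]):8.1f} x 1e-6 mm^2/s")
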