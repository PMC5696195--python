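"""ADC mapping from two-b-value diffusion-weighted MRI.

Under the mono-exponential diffusion model the DWI signal decays as
``S_b = S_0 * exp(-b * ADC)``, so a pair of acquisitions at b-values
``b_low`` (typically 0) and ``b_high`` determines the apparent diffusion
coefficient voxel-wise:

    ADC = ln(S_low / S_high) / (b_high - b_low)

ADC values are expressed throughout in 1e-6 mm^2/s (so free water at body
temperature is ~3000 and cellular tumour ~800-1100), which keeps the
magnitudes on the scale clinicians quote.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Geometry", "DwiStudy", "AdcMap", "compute_adc", "ADC_UNIT_SCALE"]

#: multiplicative factor taking ADC in mm^2/s to the reported 1e-6 mm^2/s unit
ADC_UNIT_SCALE = 1e6


@dataclass(frozen=True)
class Geometry:
    """In-plane voxel spacing (dx, dy) in mm and the distance between slice
    centres (slice thickness + gap) in mm."""

    voxel_spacing: tuple[float, float] = (1.5, 1.5)
    slice_spacing: float = 5.0

    def __post_init__(self) -> None:
        dx, dy = self.voxel_spacing
        if dx <= 0 or dy <= 0 or self.slice_spacing <= 0:
            raise ValueError("voxel_spacing and slice_spacing must be strictly positive")


@dataclass
class DwiStudy:
    """A paired two-b-value DWI acquisition.

    ``signal_b0`` and ``signal_bhigh`` are 3-D nonnegative magnitude volumes of
    identical shape; ``b_low``/``b_high`` are the diffusion weightings in
    s/mm^2 (0 and 800 for the protocol this package targets).
    """

    signal_b0: np.ndarray
    signal_bhigh: np.ndarray
    b_low: float = 0.0
    b_high: float = 800.0
    geometry: Geometry = field(default_factory=Geometry)

    def __post_init__(self) -> None:
        self.signal_b0 = np.asarray(self.signal_b0, dtype=float)
        self.signal_bhigh = np.asarray(self.signal_bhigh, dtype=float)
        if self.signal_b0.shape != self.signal_bhigh.shape:
            raise ValueError(
                f"signal volumes differ in shape: {self.signal_b0.shape} vs "
                f"{self.signal_bhigh.shape}"
            )
        if self.signal_b0.ndim != 3:
            raise ValueError("signal volumes must be 3-D")
        if not self.b_high > self.b_low >= 0:
            raise ValueError("require b_high > b_low >= 0")
        if np.nanmin(self.signal_b0) < 0 or np.nanmin(self.signal_bhigh) < 0:
            raise ValueError("signal intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.signal_b0.shape


@dataclass
class AdcMap:
    """ADC volume in 1e-6 mm^2/s with a validity mask.

    ``valid_mask`` is True where both signals were strictly positive so the
    log-ratio was computable; elsewhere ``adc`` holds NaN. ``n_negative``
    counts valid voxels whose ADC came out negative (S_high > S_low, i.e.
    noise) — these are retained, not clipped.
    """

    adc: np.ndarray
    valid_mask: np.ndarray
    geometry: Geometry
    n_negative: int = 0

    def __post_init__(self) -> None:
        if self.adc.shape != self.valid_mask.shape:
            raise ValueError("adc and valid_mask must share a shape")
        if not np.all(np.isfinite(self.adc[self.valid_mask])):
            raise ValueError("adc must be finite wherever valid_mask is true")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.adc.shape


def compute_adc(study: DwiStudy) -> AdcMap:
    """Compute the mono-exponential ADC map for a two-b-value study.

    Voxels where either signal is zero (or negative) are marked invalid and
    stored as NaN; negative ADC values from noisy voxels are kept as-is and
    tallied in ``AdcMap.n_negative``.
    """
    if study.b_high == study.b_low:
        raise ValueError("b_high must differ from b_low")
    s0 = study.signal_b0
    sb = study.signal_bhigh
    valid = (s0 > 0) & (sb > 0)
    adc = np.full(s0.shape, np.nan)
    delta_b = study.b_high - study.b_low
    with np.errstate(divide="ignore", invalid="ignore"):
        adc[valid] = np.log(s0[valid] / sb[valid]) / delta_b * ADC_UNIT_SCALE
    n_negative = int(np.count_nonzero(adc[valid] < 0))
    return AdcMap(adc=adc, valid_mask=valid, geometry=study.geometry, n_negative=n_negative)
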