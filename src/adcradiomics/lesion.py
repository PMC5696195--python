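"""Whole-lesion VOI assembly, morphology and first-order ADC histogram features.

The volume of interest (VOI) is the stack of per-slice lesion ROIs. From it we
derive the three morphological measures radiologists report (maximal tumour
diameter, total ROI area, volume) and the first-order statistics of the pooled
ADC values inside the VOI: mean, the 5/10/25/50/75/90th percentiles, skewness,
kurtosis and histogram entropy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .adc import AdcMap, Geometry

__all__ = [
    "EmptyVoiError",
    "VoiMask",
    "MorphFeatures",
    "HistogramFeatures",
    "assemble_voi",
    "morphology",
    "histogram_features",
    "PERCENTILES",
]

PERCENTILES = (5, 10, 25, 50, 75, 90)


class EmptyVoiError(ValueError):
    """Raised when an operation receives a VOI with no voxels."""


@dataclass
class VoiMask:
    """Whole-lesion binary mask with its geometry.

    ``slice_axis`` names the through-plane array axis (default: third axis).
    """

    mask: np.ndarray
    slice_axis: int = 2
    geometry: Geometry = field(default_factory=Geometry)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("VOI mask must be 3-D")
        if not self.mask.any():
            raise EmptyVoiError("VOI contains no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def slices(self):
        """Iterate (index, 2-D in-plane mask) along the slice axis."""
        for k in range(self.mask.shape[self.slice_axis]):
            yield k, np.take(self.mask, k, axis=self.slice_axis)


@dataclass(frozen=True)
class MorphFeatures:
    mtd: float  # maximal tumour diameter, mm
    area: float  # summed ROI area, mm^2
    volume: float  # VOI volume, mm^3


@dataclass(frozen=True)
class HistogramFeatures:
    adc_mean: float
    p5: float
    p10: float
    p25: float
    p50: float
    p75: float
    p90: float
    skewness: float
    kurtosis: float
    entropy: float  # bits

    def as_dict(self) -> dict[str, float]:
        return {
            "adc_mean": self.adc_mean,
            "p5": self.p5,
            "p10": self.p10,
            "p25": self.p25,
            "p50": self.p50,
            "p75": self.p75,
            "p90": self.p90,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
            "entropy": self.entropy,
        }


def assemble_voi(
    roi_slices: list[np.ndarray],
    slice_axis: int = 2,
    geometry: Geometry | None = None,
) -> VoiMask:
    """Stack per-slice binary ROIs into a whole-lesion VOI.

    Empty slices inside the stack are permitted (gaps in the lesion); an
    all-empty input raises :class:`EmptyVoiError`.
    """
    if not roi_slices:
        raise EmptyVoiError("no ROI slices given")
    arrs = [np.asarray(s).astype(bool) for s in roi_slices]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(f"ROI slices have inconsistent in-plane shapes: {shapes}")
    if arrs[0].ndim != 2:
        raise ValueError("each ROI slice must be 2-D")
    mask = np.stack(arrs, axis=slice_axis)
    if not mask.any():
        raise EmptyVoiError("all ROI slices are empty")
    return VoiMask(mask=mask, slice_axis=slice_axis, geometry=geometry or Geometry())


def _max_pairwise_distance(points_mm: np.ndarray) -> float:
    """Largest Euclidean distance between any two points, via the convex hull
    when there are enough points (the diameter is attained on the hull)."""
    if len(points_mm) == 1:
        return 0.0
    pts = points_mm
    if len(pts) > 50 and pts.shape[1] <= 3:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass  # degenerate (collinear) clouds: brute force below
    return float(pdist(pts).max())


def morphology(voi: VoiMask, mtd_mode: str = "in_plane") -> MorphFeatures:
    """Morphological features of the VOI.

    area   -- summed true-voxel count x dx x dy over all slices (mm^2)
    volume -- area x slice spacing (mm^3), i.e. each ROI extruded over one
              slice interval
    mtd    -- maximal tumour diameter: the largest distance between in-plane
              voxel centres within any single slice (the clinical caliper
              convention). ``mtd_mode='3d'`` instead takes the diameter over
              all voxel centres in 3-D.
    """
    dx, dy = voi.geometry.voxel_spacing
    dz = voi.geometry.slice_spacing
    n = voi.n_voxels
    area = n * dx * dy
    volume = area * dz

    if mtd_mode == "in_plane":
        mtd = 0.0
        for _, sl in voi.slices():
            if not sl.any():
                continue
            ij = np.argwhere(sl)
            pts = ij * np.array([dx, dy])
            mtd = max(mtd, _max_pairwise_distance(pts))
    elif mtd_mode == "3d":
        ijk = np.argwhere(voi.mask)
        scale = np.empty(3)
        inplane_axes = [ax for ax in range(3) if ax != voi.slice_axis]
        scale[inplane_axes[0]] = dx
        scale[inplane_axes[1]] = dy
        scale[voi.slice_axis] = dz
        mtd = _max_pairwise_distance(ijk * scale)
    else:
        raise ValueError("mtd_mode must be 'in_plane' or '3d'")
    return MorphFeatures(mtd=mtd, area=area, volume=volume)


def _skew_kurtosis(values: np.ndarray, convention: str) -> tuple[float, float]:
    if np.ptp(values) == 0:
        # degenerate point mass: moments undefined; report 0 by convention
        return 0.0, 0.0
    g1 = float(sps.skew(values, bias=True))
    k_excess = float(sps.kurtosis(values, fisher=True, bias=True))
    if convention == "pearson":
        return g1, k_excess + 3.0
    if convention == "excess":
        return g1, k_excess
    raise ValueError("kurtosis convention must be 'pearson' or 'excess'")


def histogram_features(
    adc: AdcMap,
    voi: VoiMask,
    bins: int = 128,
    kurtosis_convention: str = "pearson",
    on_invalid: str = "drop",
) -> HistogramFeatures:
    """First-order statistics of the ADC values pooled over the VOI.

    Percentiles use linear interpolation. Skewness is the Fisher moment
    coefficient g1. Kurtosis defaults to the non-excess (Pearson) convention
    where a normal distribution scores 3. Entropy is -sum p_i log2 p_i over a
    ``bins``-bin equal-width histogram spanning the VOI's own value range, so
    absolute entropies are only comparable at a fixed ``bins``.

    ``on_invalid`` controls VOI voxels falling outside the ADC validity mask:
    'drop' discards them with a warning, 'error' raises.
    """
    if bins < 1:
        raise ValueError("bins must be a positive integer")
    if adc.shape != voi.mask.shape:
        raise ValueError("ADC map and VOI mask shapes differ")
    inside = voi.mask
    invalid = inside & ~adc.valid_mask
    n_invalid = int(invalid.sum())
    if n_invalid:
        if on_invalid == "error":
            raise ValueError(f"{n_invalid} VOI voxels have no valid ADC value")
        if on_invalid != "drop":
            raise ValueError("on_invalid must be 'drop' or 'error'")
        warnings.warn(f"dropping {n_invalid} VOI voxels with invalid ADC", stacklevel=2)
        inside = inside & adc.valid_mask
        if not inside.any():
            raise EmptyVoiError("no valid ADC voxels remain in the VOI")
    values = adc.adc[inside]

    pcts = np.percentile(values, PERCENTILES)  # linear interpolation
    skew, kurt = _skew_kurtosis(values, kurtosis_convention)

    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        entropy = 0.0
    else:
        counts, _ = np.histogram(values, bins=bins, range=(vmin, vmax))
        p = counts[counts > 0] / values.size
        entropy = float(-(p * np.log2(p)).sum())

    return HistogramFeatures(
        adc_mean=float(values.mean()),
        p5=float(pcts[0]),
        p10=float(pcts[1]),
        p25=float(pcts[2]),
        p50=float(pcts[3]),
        p75=float(pcts[4]),
        p90=float(pcts[5]),
        skewness=skew,
        kurtosis=kurt,
        entropy=entropy,
    )
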