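"""Synthetic inputs at two fidelity levels.

Feature-level cohorts
    Per-patient feature tables drawn from the published per-group summary
    statistics of a 36-patient cervical-cancer CCRT study (26 nonrecurrence /
    10 recurrence): histogram and morphological features as independent
    normals from the printed mean +/- SD, texture features as lognormals
    matched to the printed median (IQR). These let every statistical routine
    be exercised on cohorts whose group-level distributions match the study.

Image-level phantoms
    Two-b-value DWI volumes containing an ellipsoidal lesion with a smooth
    low-ADC solid compartment and optional high-ADC necrotic foci (thresholded
    smoothed noise, so texture sees realistic spatial correlation), Rician
    noise on the magnitude signals, and a second observer's mask produced by
    morphological perturbation. Ground truth (exact ADC field, compartment
    labels, necrotic fraction) is returned alongside.

Default geometry mirrors a pelvic DWI protocol: 4 mm slices + 1 mm gap and
~1.5 mm in-plane resolution (24 cm FOV / 157 matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .adc import ADC_UNIT_SCALE, DwiStudy, Geometry
from .lesion import VoiMask

__all__ = [
    "GeometryError",
    "HISTOGRAM_STATS",
    "TEXTURE_STATS",
    "MORPHOLOGY_STATS",
    "GROUP_SIZES",
    "FeatureCohortSpec",
    "simulate_feature_cohort",
    "PhantomSpec",
    "PhantomResult",
    "simulate_phantom",
    "two_arm_phantom_specs",
]


class GeometryError(ValueError):
    """Raised when a requested lesion does not fit inside the phantom volume."""


# ---------------------------------------------------------------------------
# published per-group summary statistics (feature -> (nonrecurrence, recurrence))
# ---------------------------------------------------------------------------

#: (mean, SD) per group; ADC features in 1e-6 mm^2/s
HISTOGRAM_STATS: dict[str, dict[str, tuple[tuple[float, float], tuple[float, float]]]] = {
    "pre": {
        "adc_mean": ((1064.76, 67.44), (983.71, 127.25)),
        "p5": ((726.38, 134.77), (699.90, 170.40)),
        "p10": ((784.54, 121.82), (752.60, 160.58)),
        "p25": ((876.00, 109.89), (838.10, 145.96)),
        "p50": ((999.31, 90.45), (943.10, 136.08)),
        "p75": ((1201.46, 73.89), (1090.10, 125.99)),
        "p90": ((1448.50, 146.79), (1273.30, 122.28)),
        "skewness": ((2.23, 1.11), (1.91, 0.79)),
        "kurtosis": ((12.93, 9.22), (11.14, 5.05)),
        "entropy": ((6.23, 0.58), (6.10, 0.27)),
    },
    "mid": {
        "adc_mean": ((1333.24, 123.96), (1171.21, 108.11)),
        "p5": ((975.60, 204.60), (833.33, 169.51)),
        "p10": ((1054.70, 184.67), (902.44, 146.32)),
        "p25": ((1161.75, 159.14), (1006.89, 132.06)),
        "p50": ((1292.55, 135.23), (1147.67, 116.64)),
        "p75": ((1472.70, 121.57), (1297.00, 111.84)),
        "p90": ((1665.95, 140.67), (1482.67, 196.97)),
        "skewness": ((1.38, 1.09), (1.14, 1.30)),
        "kurtosis": ((8.99, 6.82), (8.17, 7.04)),
        "entropy": ((5.75, 0.93), (5.68, 0.69)),
    },
}

#: (median, q1, q3) per group
TEXTURE_STATS: dict[str, dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]]] = {
    "pre": {
        "correlation": ((8.76, 6.17, 12.59), (23.98, 12.73, 34.98)),
        "autocorrelation": ((88689.45, 73619.12, 101094.67), (62330.77, 55900.31, 71437.64)),
        "entropy_h": ((11.31, 9.07, 12.18), (11.30, 10.43, 11.75)),
        "homogeneity": ((8561.20, 6976.18, 10457.48), (9823.74, 6774.34, 10661.50)),
    },
    "mid": {
        "correlation": ((14.87, 6.65, 24.34), (23.78, 20.25, 39.13)),
        "autocorrelation": ((119709.75, 104566.62, 137939.81), (93120.65, 73795.97, 106326.00)),
        "entropy_h": ((10.20, 7.55, 11.50), (9.92, 8.69, 11.66)),
        "homogeneity": ((7150.19, 6082.49, 8873.28), (9071.10, 7078.09, 10696.41)),
    },
}

#: (mean, SD) per group; MTD mm, area mm^2, volume mm^3
MORPHOLOGY_STATS: dict[str, dict[str, tuple[tuple[float, float], tuple[float, float]]]] = {
    "pre": {
        "mtd": ((50.88, 12.18), (46.43, 12.69)),
        "area": ((7158.69, 4799.17), (4629.76, 3682.28)),
        "volume": ((37722.58, 24177.35), (25585.26, 22700.66)),
    },
    "mid": {
        "mtd": ((38.19, 14.53), (39.01, 15.32)),
        "area": ((3784.85, 3888.81), (2799.83, 3168.86)),
        "volume": ((19566.62, 20111.85), (14221.14, 15742.34)),
    },
}

#: study group sizes: (nonrecurrence, recurrence)
GROUP_SIZES = (26, 10)

_Z75 = 0.6744897501960817  # standard normal 75th-percentile quantile


@dataclass(frozen=True)
class FeatureCohortSpec:
    """Parameters of a feature-level two-group cohort draw."""

    timepoint: str = "pre"
    n_nonrecurrence: int = GROUP_SIZES[0]
    n_recurrence: int = GROUP_SIZES[1]
    include_morphology: bool = True
    include_histogram: bool = True
    include_texture: bool = True
    texture_distribution: str = "lognormal"  # or 'normal' (moments matched to the IQR)

    def __post_init__(self) -> None:
        if self.timepoint not in ("pre", "mid"):
            raise ValueError("timepoint must be 'pre' or 'mid'")
        if self.n_nonrecurrence < 1 or self.n_recurrence < 1:
            raise ValueError("group sizes must be >= 1")


def _lognormal_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of a lognormal matching a printed median and IQR."""
    mu = np.log(median)
    sigma = (np.log(q3) - np.log(q1)) / (2 * _Z75)
    return mu, sigma


def simulate_feature_cohort(
    spec: FeatureCohortSpec = FeatureCohortSpec(),
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw a reproducible two-group feature table from the printed statistics.

    Features are drawn independently (the study reports no within-patient
    correlations). Rows carry ``patient_id``, ``timepoint`` and ``outcome``
    ('nonrecurrence'/'recurrence').
    """
    rng = np.random.default_rng(rng)
    n0, n1 = spec.n_nonrecurrence, spec.n_recurrence
    rows: dict[str, np.ndarray] = {}

    blocks: list[tuple[dict, str]] = []
    if spec.include_morphology:
        blocks.append((MORPHOLOGY_STATS[spec.timepoint], "normal"))
    if spec.include_histogram:
        blocks.append((HISTOGRAM_STATS[spec.timepoint], "normal"))
    if spec.include_texture:
        blocks.append((TEXTURE_STATS[spec.timepoint], spec.texture_distribution))

    for stats_block, dist in blocks:
        for feature, (g_non, g_rec) in stats_block.items():
            vals = []
            for params, n in ((g_non, n0), (g_rec, n1)):
                if dist == "normal" and len(params) == 2:
                    m, sd = params
                    vals.append(m + sd * rng.standard_normal(n) if sd > 0 else np.full(n, m))
                elif dist == "normal":
                    med, q1, q3 = params
                    sd = (q3 - q1) / (2 * _Z75)
                    vals.append(med + sd * rng.standard_normal(n))
                else:
                    med, q1, q3 = params
                    mu, sigma = _lognormal_params(med, q1, q3)
                    vals.append(np.exp(mu + sigma * rng.standard_normal(n)))
            rows[feature] = np.concatenate(vals)

    df = pd.DataFrame(rows)
    df.insert(0, "outcome", ["nonrecurrence"] * n0 + ["recurrence"] * n1)
    df.insert(0, "timepoint", spec.timepoint)
    df.insert(0, "patient_id", [f"P{i:03d}" for i in range(1, n0 + n1 + 1)])
    return df


# ---------------------------------------------------------------------------
# image-level phantoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue parameters of a two-compartment lesion phantom."""

    shape: tuple[int, int, int] = (64, 64, 10)
    voxel_spacing: tuple[float, float] = (1.5, 1.5)  # mm
    slice_spacing: float = 5.0  # mm (4 mm slice + 1 mm gap)
    lesion_center: tuple[float, float, float] | None = None  # voxel coords
    lesion_axes_mm: tuple[float, float, float] = (16.0, 13.0, 11.0)  # semi-axes
    solid_adc_mean: float = 950.0  # 1e-6 mm^2/s
    solid_adc_sd: float = 120.0
    necrotic_adc_mean: float = 2200.0
    necrotic_adc_sd: float = 150.0
    necrotic_fraction: float = 0.15
    smoothness_vox: float = 2.0  # in-plane Gaussian correlation length
    background_adc_mean: float = 1600.0
    background_adc_sd: float = 120.0
    s0: float = 1000.0  # baseline b=0 signal
    rician_sigma: float = 8.0
    observer_perturb_vox: int = 1
    b_high: float = 800.0

    def __post_init__(self) -> None:
        if not 0 <= self.necrotic_fraction < 1:
            raise ValueError("necrotic_fraction must be in [0, 1)")
        if min(self.solid_adc_sd, self.necrotic_adc_sd, self.background_adc_sd) < 0:
            raise ValueError("ADC SDs must be nonnegative")
        if self.rician_sigma < 0:
            raise ValueError("rician_sigma must be nonnegative")


@dataclass
class PhantomResult:
    study: DwiStudy
    adc_truth: np.ndarray  # noise-free ADC field, 1e-6 mm^2/s
    mask_obs1: VoiMask
    mask_obs2: VoiMask
    truth: dict = field(default_factory=dict)


def _smooth_unit_field(
    rng: np.random.Generator, shape: tuple[int, ...], sigma_inplane: float, aspect: float
) -> np.ndarray:
    """Gaussian-filtered white noise rescaled to unit variance."""
    g = rng.standard_normal(shape)
    if sigma_inplane > 0:
        g = ndi.gaussian_filter(g, sigma=(sigma_inplane, sigma_inplane, sigma_inplane * aspect))
    sd = g.std()
    return g / sd if sd > 0 else g


def simulate_phantom(
    spec: PhantomSpec = PhantomSpec(),
    rng: np.random.Generator | int | None = None,
) -> PhantomResult:
    """Simulate one two-b-value DWI study with a heterogeneous lesion.

    The noise-free ADC field is a smooth Gaussian random field around the
    solid-compartment mean, with necrotic foci (high ADC) carved out of the
    lesion as thresholded smoothed noise covering ~``necrotic_fraction`` of
    the lesion. Signals follow the mono-exponential model with Rician noise
    applied to both magnitude volumes. Observer 2's mask is a seeded
    dilation or erosion of the true lesion mask.
    """
    rng = np.random.default_rng(rng)
    nx, ny, nz = spec.shape
    dx, dy = spec.voxel_spacing
    dz = spec.slice_spacing
    geometry = Geometry(voxel_spacing=(dx, dy), slice_spacing=dz)

    center = spec.lesion_center or ((nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2)
    ax, ay, az = spec.lesion_axes_mm
    # lesion must fit inside the volume
    if (
        ax / dx > center[0]
        or ax / dx > nx - 1 - center[0]
        or ay / dy > center[1]
        or ay / dy > ny - 1 - center[1]
        or az / dz > center[2]
        or az / dz > nz - 1 - center[2]
    ):
        raise GeometryError("lesion ellipsoid does not fit inside the phantom volume")

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    lesion = (
        ((ii - center[0]) * dx / ax) ** 2
        + ((jj - center[1]) * dy / ay) ** 2
        + ((kk - center[2]) * dz / az) ** 2
    ) <= 1.0
    if not lesion.any():
        raise GeometryError("lesion ellipsoid contains no voxels")

    aspect = dx / dz  # shrink through-plane smoothing to stay ~isotropic in mm
    g_solid = _smooth_unit_field(rng, spec.shape, spec.smoothness_vox, aspect)
    g_nec_shape = _smooth_unit_field(rng, spec.shape, max(spec.smoothness_vox, 1.5), aspect)
    g_nec_vals = _smooth_unit_field(rng, spec.shape, spec.smoothness_vox, aspect)
    g_bg = _smooth_unit_field(rng, spec.shape, 3.0, aspect)

    adc = spec.background_adc_mean + spec.background_adc_sd * g_bg
    adc[lesion] = spec.solid_adc_mean + spec.solid_adc_sd * g_solid[lesion]

    necrotic = np.zeros(spec.shape, bool)
    if spec.necrotic_fraction > 0:
        thr = np.quantile(g_nec_shape[lesion], 1.0 - spec.necrotic_fraction)
        necrotic = lesion & (g_nec_shape > thr)
        adc[necrotic] = spec.necrotic_adc_mean + spec.necrotic_adc_sd * g_nec_vals[necrotic]

    adc = np.maximum(adc, 50.0)  # keep diffusivities physical

    s0 = np.full(spec.shape, spec.s0)
    sb = spec.s0 * np.exp(-spec.b_high * adc / ADC_UNIT_SCALE)
    if spec.rician_sigma > 0:
        sig = spec.rician_sigma
        s0 = np.sqrt((s0 + rng.normal(0, sig, spec.shape)) ** 2 + rng.normal(0, sig, spec.shape) ** 2)
        sb = np.sqrt((sb + rng.normal(0, sig, spec.shape)) ** 2 + rng.normal(0, sig, spec.shape) ** 2)

    study = DwiStudy(signal_b0=s0, signal_bhigh=sb, b_low=0.0, b_high=spec.b_high, geometry=geometry)

    mask2 = lesion
    if spec.observer_perturb_vox > 0:
        r = spec.observer_perturb_vox
        if rng.random() < 0.5:
            eroded = ndi.binary_erosion(lesion, iterations=r)
            mask2 = eroded if eroded.any() else ndi.binary_dilation(lesion, iterations=r)
        else:
            mask2 = ndi.binary_dilation(lesion, iterations=r)

    truth = {
        "necrotic_fraction_target": spec.necrotic_fraction,
        "necrotic_fraction_actual": float(necrotic.sum() / lesion.sum()),
        "lesion_volume_mm3": float(lesion.sum() * dx * dy * dz),
        "lesion_adc_mean": float(adc[lesion].mean()),
        "necrotic_mask": necrotic,
        "adc_field": adc,
    }
    return PhantomResult(
        study=study,
        adc_truth=adc,
        mask_obs1=VoiMask(mask=lesion, slice_axis=2, geometry=geometry),
        mask_obs2=VoiMask(mask=mask2, slice_axis=2, geometry=geometry),
        truth=truth,
    )


def two_arm_phantom_specs(base: PhantomSpec = PhantomSpec()) -> dict[str, PhantomSpec]:
    """Study conditions for a two-arm phantom cohort.

    The 'nonrecurrence' arm carries substantial necrosis (high-ADC foci raise
    the upper ADC percentiles) and a smoother solid compartment; the
    'recurrence' arm is mostly solid with a slightly lower solid-compartment
    ADC and shorter spatial correlation (more heterogeneous texture). These
    directions mirror the clinical interpretation that recurrence-prone
    tumours are more solid (lower 75th/90th percentiles) and more
    heterogeneous (lower autocorrelation).
    """
    return {
        "nonrecurrence": replace(
            base, necrotic_fraction=0.30, solid_adc_mean=1000.0, solid_adc_sd=110.0, smoothness_vox=2.5
        ),
        "recurrence": replace(
            base, necrotic_fraction=0.05, solid_adc_mean=930.0, solid_adc_sd=130.0, smoothness_vox=1.2
        ),
    }
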