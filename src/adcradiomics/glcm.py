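"""Gray-level co-occurrence matrices within a lesion VOI and four texture
features: correlation, autocorrelation, entropy(H) and homogeneity.

The GLCM P(i, j) records how often gray levels i and j occur at a fixed voxel
offset. Co-occurrence is accumulated in 2-D, per slice, for the four in-plane
direction angles 0/45/90/135 degrees at a configurable voxel distance, summed
over every slice of the VOI — DWI slices are thick relative to the in-plane
resolution, so through-plane neighbours are not texture at the same scale.
Features are evaluated per direction and then averaged (feature averaging;
matrix averaging is available as an option).

Feature formulas, for a (usually probability-normalized) matrix P with levels
1..G:

    correlation     = sum_ij (i - mu)(j - mu) P(i,j) / sigma^2
    autocorrelation = sum_ij i * j * P(i,j)
    entropy(H)      = -sum_ij P(i,j) log2 P(i,j)
    homogeneity     = sum_ij P(i,j) / (1 + (i - j)^2)

Two dialects exist in the literature for mu/sigma in the correlation formula:
the marginal gray-level distribution's mean/SD (default; bounds correlation in
[-1, 1]) or the mean/SD of the matrix elements themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .adc import AdcMap
from .lesion import VoiMask

__all__ = [
    "ANGLES",
    "QuantizedVolume",
    "GlcmSet",
    "TextureFeatures",
    "quantize",
    "build_glcm",
    "texture_features",
]

#: in-plane (row, col) unit offsets per direction angle in degrees
ANGLES: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}


@dataclass
class QuantizedVolume:
    """Integer gray levels in 1..G on VOI voxels (0 outside the VOI)."""

    levels: np.ndarray
    G: int
    method: str
    edges: np.ndarray | None  # inner bin edges for equal-width binning
    voi: VoiMask

    def __post_init__(self) -> None:
        inside = self.voi.mask
        lv = self.levels[inside]
        if lv.min() < 1 or lv.max() > self.G:
            raise ValueError("levels on VOI voxels must lie in [1, G]")


@dataclass
class GlcmSet:
    """One co-occurrence matrix per direction angle.

    ``pair_counts`` holds the raw number of accumulated voxel pairs per
    direction; directions with zero pairs carry an all-zero matrix and are
    skipped (with a warning already issued) by :func:`texture_features`.
    """

    matrices: dict[int, np.ndarray]
    pair_counts: dict[int, int]
    G: int
    distance: int
    symmetric: bool
    normalized: bool

    def nonempty_angles(self) -> list[int]:
        return [a for a, c in self.pair_counts.items() if c > 0]


@dataclass(frozen=True)
class TextureFeatures:
    correlation: float
    autocorrelation: float
    entropy_h: float  # bits
    homogeneity: float
    degenerate: bool = False  # single occupied level: correlation forced to 0

    def as_dict(self) -> dict[str, float]:
        return {
            "correlation": self.correlation,
            "autocorrelation": self.autocorrelation,
            "entropy_h": self.entropy_h,
            "homogeneity": self.homogeneity,
        }


def quantize(
    adc: AdcMap,
    voi: VoiMask,
    G: int = 64,
    method: str = "equal_width",
    bin_width: float | None = None,
) -> QuantizedVolume:
    """Map VOI ADC values to integer gray levels 1..G.

    'equal_width' (default): G equal bins spanning the VOI's min-max range;
    boundary values fall in the lower bin, a constant VOI maps to level 1.
    'fixed_width': level = floor(value / bin_width) + 1, an absolute-scale
    binning whose G is set by the largest observed level; values below zero
    are clamped to level 1.
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    if adc.shape != voi.mask.shape:
        raise ValueError("ADC map and VOI mask shapes differ")
    inside = voi.mask & adc.valid_mask
    if not inside.any():
        raise ValueError("no valid ADC voxels in the VOI")
    values = adc.adc[inside]
    levels = np.zeros(adc.shape, dtype=np.int32)

    if method == "equal_width":
        vmin, vmax = values.min(), values.max()
        if vmin == vmax:
            lv = np.ones(values.shape, dtype=np.int32)
            edges = None
        else:
            edges = vmin + (vmax - vmin) / G * np.arange(1, G)
            lv = (np.digitize(values, edges, right=True) + 1).astype(np.int32)
    elif method == "fixed_width":
        if bin_width is None or bin_width <= 0:
            raise ValueError("fixed_width quantization needs a positive bin_width")
        lv = np.maximum(np.floor(values / bin_width).astype(np.int64) + 1, 1).astype(np.int32)
        G = int(lv.max())
        edges = None
    else:
        raise ValueError("method must be 'equal_width' or 'fixed_width'")

    levels[inside] = lv
    return QuantizedVolume(levels=levels, G=G, method=method, edges=edges, voi=voi)


def build_glcm(
    q: QuantizedVolume,
    distance: int = 1,
    symmetric: bool = True,
    normalize: bool = True,
) -> GlcmSet:
    """Accumulate per-slice 2-D co-occurrence matrices over the whole VOI.

    For each direction, ordered pairs of gray levels at the given offset are
    counted when both endpoints lie inside the VOI, summed across slices.
    Symmetric accumulation counts each pair in both orders. Normalization
    divides each direction's matrix by its pair total so it sums to one.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    voi = q.voi
    G = q.G
    matrices = {a: np.zeros((G, G)) for a in ANGLES}
    pair_counts = dict.fromkeys(ANGLES, 0)

    for k in range(voi.mask.shape[voi.slice_axis]):
        inside = np.take(voi.mask, k, axis=voi.slice_axis)
        lev = np.take(q.levels, k, axis=voi.slice_axis)
        if not inside.any():
            continue
        nr, nc = inside.shape
        for angle, (dr0, dc0) in ANGLES.items():
            dr, dc = dr0 * distance, dc0 * distance
            # source/destination windows for the (dr, dc) shift
            r0s, r0e = max(0, -dr), min(nr, nr - dr)
            c0s, c0e = max(0, -dc), min(nc, nc - dc)
            if r0s >= r0e or c0s >= c0e:
                continue
            src = (slice(r0s, r0e), slice(c0s, c0e))
            dst = (slice(r0s + dr, r0e + dr), slice(c0s + dc, c0e + dc))
            ok = inside[src] & inside[dst]
            if not ok.any():
                continue
            a = lev[src][ok] - 1
            b = lev[dst][ok] - 1
            np.add.at(matrices[angle], (a, b), 1)
            pair_counts[angle] += int(ok.sum())

    for angle in ANGLES:
        if symmetric:
            matrices[angle] = matrices[angle] + matrices[angle].T
            pair_counts[angle] *= 2
        if pair_counts[angle] == 0:
            warnings.warn(
                f"no co-occurring VOI voxel pairs in the {angle} deg direction; "
                "this direction will be excluded from feature averaging",
                stacklevel=2,
            )
        elif normalize:
            matrices[angle] = matrices[angle] / matrices[angle].sum()

    return GlcmSet(
        matrices=matrices,
        pair_counts=pair_counts,
        G=G,
        distance=distance,
        symmetric=symmetric,
        normalized=normalize,
    )


def _features_of_matrix(P: np.ndarray, sigma_dialect: str) -> tuple[float, float, float, float, bool]:
    G = P.shape[0]
    idx = np.arange(1, G + 1, dtype=float)
    i = idx[:, None]
    j = idx[None, :]

    autocorr = float((i * j * P).sum())
    pos = P[P > 0]
    entropy_h = float(-(pos * np.log2(pos)).sum()) if pos.size else 0.0
    homogeneity = float((P / (1.0 + (i - j) ** 2)).sum())

    degenerate = False
    if sigma_dialect == "marginal":
        total = P.sum()
        if total == 0:
            return 0.0, autocorr, entropy_h, homogeneity, True
        # marginal over rows; equals the column marginal for symmetric P
        p_i = P.sum(axis=1) / total
        mu = float((idx * p_i).sum())
        var = float(((idx - mu) ** 2 * p_i).sum())
        cov = float(((i - mu) * (j - mu) * (P / total)).sum())
        if var == 0:
            correlation, degenerate = 0.0, True
        else:
            correlation = cov / var
    elif sigma_dialect == "element":
        mu = float(P.mean())
        sd = float(P.std())
        if sd == 0:
            correlation, degenerate = 0.0, True
        else:
            correlation = float((((i - mu) * (j - mu)) * P).sum()) / sd**2
    else:
        raise ValueError("sigma_dialect must be 'marginal' or 'element'")
    return correlation, autocorr, entropy_h, homogeneity, degenerate


def texture_features(
    glcms: GlcmSet,
    sigma_dialect: str = "marginal",
    direction_average: str = "features",
) -> TextureFeatures:
    """Evaluate the four texture formulas and average over directions.

    ``direction_average='features'`` (default) computes each feature per
    direction and averages the four values; ``'matrices'`` averages the
    matrices first and evaluates the formulas once.
    """
    angles = glcms.nonempty_angles()
    if not angles:
        raise ValueError("no direction of the GLCM set contains any voxel pair")

    if direction_average == "matrices":
        P = np.mean([glcms.matrices[a] for a in angles], axis=0)
        corr, auto, ent, hom, degen = _features_of_matrix(P, sigma_dialect)
        return TextureFeatures(corr, auto, ent, hom, degen)
    if direction_average != "features":
        raise ValueError("direction_average must be 'features' or 'matrices'")

    rows = [_features_of_matrix(glcms.matrices[a], sigma_dialect) for a in angles]
    arr = np.array([r[:4] for r in rows])
    degen = any(r[4] for r in rows)
    corr, auto, ent, hom = arr.mean(axis=0)
    return TextureFeatures(float(corr), float(auto), float(ent), float(hom), degen)
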