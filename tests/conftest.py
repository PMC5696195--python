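import numpy as np
import pytest

from adcradiomics.adc import AdcMap, Geometry
from adcradiomics.glcm import QuantizedVolume, build_glcm
from adcradiomics.lesion import VoiMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_adc_map(values: np.ndarray, geometry: Geometry | None = None) -> AdcMap:
    """Wrap a raw 3-D value array as an AdcMap (NaN marks invalid voxels)."""
    values = np.asarray(values, float)
    return AdcMap(adc=values, valid_mask=np.isfinite(values), geometry=geometry or Geometry())


def glcm_from_levels(levels2d: np.ndarray, mask2d: np.ndarray | None = None, **kwargs):
    """Build a GLCM set directly from a 2-D integer level image (one slice)."""
    levels2d = np.asarray(levels2d, dtype=np.int32)
    if mask2d is None:
        mask2d = np.ones_like(levels2d, dtype=bool)
    voi = VoiMask(mask=mask2d[:, :, None], slice_axis=2)
    lv3 = np.where(mask2d, levels2d, 0)[:, :, None]
    q = QuantizedVolume(
        levels=lv3, G=int(levels2d[mask2d].max()), method="equal_width", edges=None, voi=voi
    )
    return build_glcm(q, **kwargs)


def brute_force_glcm(
    levels2d: np.ndarray,
    mask2d: np.ndarray,
    offset: tuple[int, int],
    G: int,
    symmetric: bool = True,
    normalize: bool = True,
) -> np.ndarray:
    """Exhaustive double loop over voxel pairs: the independent GLCM oracle."""
    M = np.zeros((G, G))
    nr, nc = levels2d.shape
    dr, dc = offset
    for r in range(nr):
        for c in range(nc):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nr and 0 <= c2 < nc and mask2d[r, c] and mask2d[r2, c2]:
                M[levels2d[r, c] - 1, levels2d[r2, c2] - 1] += 1
    if symmetric:
        M = M + M.T
    if normalize and M.sum() > 0:
        M = M / M.sum()
    return M
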