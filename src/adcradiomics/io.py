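"""NIfTI-1 volume I/O with geometry handling."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .adc import Geometry

__all__ = ["load_volume", "save_volume", "load_mask", "save_mask", "geometry_from_header"]


def geometry_from_header(img: nib.Nifti1Image) -> Geometry:
    zooms = img.header.get_zooms()[:3]
    return Geometry(voxel_spacing=(float(zooms[0]), float(zooms[1])), slice_spacing=float(zooms[2]))


def load_volume(path: str | Path) -> tuple[np.ndarray, Geometry]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), geometry_from_header(img)


def save_volume(path: str | Path, data: np.ndarray, geometry: Geometry) -> None:
    dx, dy = geometry.voxel_spacing
    affine = np.diag([dx, dy, geometry.slice_spacing, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def load_mask(path: str | Path) -> tuple[np.ndarray, Geometry]:
    data, geom = load_volume(path)
    return data > 0.5, geom


def save_mask(path: str | Path, mask: np.ndarray, geometry: Geometry) -> None:
    dx, dy = geometry.voxel_spacing
    affine = np.diag([dx, dy, geometry.slice_spacing, 1.0])
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))
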