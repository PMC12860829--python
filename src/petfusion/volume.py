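"""Core imaging containers and NIfTI I/O.

The unit of imaging data throughout the package is :class:`Volume3D`: a 3D
scalar grid (PET uptake, SUVR, z-scores or saliency) together with voxel
spacing in millimetres and a boolean brain mask.  Parcellations are carried
by :class:`AtlasLabels`, an integer label grid plus a label -> region-name
registry.  World coordinates are intentionally ignored: volumes are assumed
spatially aligned (phantoms are born aligned), so the NIfTI affine only
encodes voxel spacing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Volume3D", "AtlasLabels", "AttributionVolume", "read_volume", "write_volume"]


@dataclass
class Volume3D:
    """A 3D scalar image with voxel spacing (mm) and a boolean brain mask."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.mask is None:
            self.mask = np.isfinite(self.data) & (self.data != 0)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape:
            raise ValueError("data and mask must share one shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy_with(self, data: np.ndarray) -> "Volume3D":
        return Volume3D(data=data, spacing=self.spacing, mask=self.mask.copy())


@dataclass
class AtlasLabels:
    """Integer parcellation grid (0 = background) plus label registry."""

    labels: np.ndarray
    registry: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.registry)
        if missing:
            raise ValueError(f"labels missing from registry: {sorted(missing)}")
        names = list(self.registry.values())
        if len(names) != len(set(names)):
            raise ValueError("region names must be unique")

    @property
    def label_ids(self) -> list[int]:
        return sorted(self.registry)

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class AttributionVolume:
    """Non-negative saliency grid in input geometry, normalized to [0, 1]."""

    data: np.ndarray
    target_class: int | None = None
    source: str = "layer_cam"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("attribution map must be 3-D")
        if self.data.size and (self.data.min() < -1e-9 or self.data.max() > 1 + 1e-9):
            raise ValueError("attribution values must lie in [0, 1]")

    def as_volume(self) -> Volume3D:
        return Volume3D(self.data, self.spacing, mask=np.ones(self.data.shape, bool))


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def read_volume(path: str | os.PathLike, mask_path: str | os.PathLike | None = None) -> Volume3D:
    """Read a NIfTI-1 volume; default mask keeps finite, nonzero voxels."""
    if not os.path.exists(path):
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D image, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive voxel spacing in header: {spacing}")
    mask = None
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        mask = np.asarray(mimg.dataobj) > 0
    vol = Volume3D(data=np.nan_to_num(data, nan=0.0), spacing=spacing,
                   mask=mask if mask is not None else (np.isfinite(data) & (data != 0)))
    return vol


def write_volume(volume: Volume3D, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1 (float32 grid, spacing in the affine)."""
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), _affine(volume.spacing))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_labels(atlas: AtlasLabels, spacing: tuple[float, float, float], path: str) -> None:
    img = nib.Nifti1Image(np.asarray(atlas.labels, dtype=np.int16), _affine(spacing))
    nib.save(img, str(path))
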