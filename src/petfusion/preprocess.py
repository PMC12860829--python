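"""Image normalization chain: Gaussian smoothing, SUVR, per-image z-score.

The chain mirrors standard FDG-PET preprocessing: spatially normalized
volumes are smoothed with an isotropic Gaussian (FWHM in millimetres,
converted per-axis to voxel sigmas), intensity-normalized to the whole-brain
mean (SUVR), and z-scored over the brain mask before entering the neural
channels.  Conventions (documented, configurable at call sites):

* sigma_voxels = fwhm_mm / (2 * sqrt(2 * ln 2)) / spacing, per axis;
* smoothing uses reflect boundary handling and leaves the mask unchanged;
* the SUVR reference is the mean over the brain mask;
* image z-scores use the population (ddof=0) standard deviation over the
  mask; voxels outside the mask are set to 0.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume import Volume3D

__all__ = ["fwhm_to_sigma", "gaussian_smooth", "to_suvr", "zscore_image"]

_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm_mm: float, spacing: tuple[float, float, float]) -> tuple[float, ...]:
    """Per-axis Gaussian sigma in voxels for an isotropic FWHM in mm."""
    return tuple(fwhm_mm / _FWHM_FACTOR / s for s in spacing)


def gaussian_smooth(volume: Volume3D, fwhm_mm: float) -> Volume3D:
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return volume.copy_with(volume.data.copy())
    sigma = fwhm_to_sigma(fwhm_mm, volume.spacing)
    smoothed = ndimage.gaussian_filter(np.asarray(volume.data, dtype=np.float64),
                                       sigma=sigma, mode="reflect")
    return volume.copy_with(smoothed)


def _masked(volume: Volume3D, mask: np.ndarray | None) -> np.ndarray:
    m = volume.mask if mask is None else np.asarray(mask, dtype=bool)
    if m.shape != volume.data.shape:
        raise ValueError("mask shape mismatch")
    if not m.any():
        raise ValueError("mask is empty")
    return m


def to_suvr(volume: Volume3D, mask: np.ndarray | None = None) -> Volume3D:
    """Divide by the mean intensity over the (brain) mask."""
    m = _masked(volume, mask)
    ref = float(np.mean(volume.data[m]))
    if ref <= 0:
        raise ValueError(f"mask mean must be positive, got {ref}")
    return volume.copy_with(np.asarray(volume.data, dtype=np.float64) / ref)


def zscore_image(volume: Volume3D, mask: np.ndarray | None = None) -> Volume3D:
    """(x - mean) / sd over mask voxels (population sd); 0 outside the mask."""
    m = _masked(volume, mask)
    vals = volume.data[m]
    mu = float(vals.mean())
    sd = float(vals.std(ddof=0))
    if sd <= 0:
        raise ValueError("zero variance over mask")
    out = np.zeros(volume.data.shape, dtype=np.float64)
    out[m] = (vals - mu) / sd
    return volume.copy_with(out)
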