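"""Fixed-bin-width gray-level discretization of a region of interest."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..volume import Volume3D

__all__ = ["DiscreteROI", "discretize"]


@dataclass
class DiscreteROI:
    """Discretized ROI: level grid over the bounding box, 0 outside the ROI.

    Levels are integers in 1..Ng with ``level = floor((x - min)/bin_width) + 1``
    (an exact-multiple maximum opens one extra bin, matching the fixed-bin-width
    convention of standard radiomics banks); a constant ROI has Ng = 1.
    """

    levels: np.ndarray            # int grid on the bounding box, 0 outside ROI
    mask: np.ndarray              # bool grid on the bounding box
    values: np.ndarray            # raw ROI intensities (1-D, ROI voxels)
    n_levels: int
    bin_width: float
    spacing: tuple[float, float, float]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def roi_levels(self) -> np.ndarray:
        """1-D vector of levels over ROI voxels."""
        return self.levels[self.mask]


def _crop(mask: np.ndarray, pad: int = 1):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, mask.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def discretize(volume: Volume3D, roi_mask: np.ndarray, bin_width: float) -> DiscreteROI:
    """Discretize ROI intensities into fixed-width bins anchored at the ROI min."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != volume.data.shape:
        raise ValueError("ROI mask shape mismatch")
    if not roi_mask.any():
        raise ValueError("empty ROI")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    box = _crop(roi_mask)
    mask = roi_mask[box]
    data = np.asarray(volume.data, dtype=np.float64)[box]
    vals = data[mask]
    mn = vals.min()
    levels = np.zeros(mask.shape, dtype=np.int32)
    levels[mask] = np.floor((vals - mn) / bin_width).astype(np.int32) + 1
    ng = int(levels.max())
    return DiscreteROI(levels=levels, mask=mask, values=vals, n_levels=max(ng, 1),
                       bin_width=float(bin_width), spacing=volume.spacing)
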