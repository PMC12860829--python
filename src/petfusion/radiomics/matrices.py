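"""Texture matrices (GLCM, GLRLM, GLSZM, NGTDM, GLDM) on discretized ROIs.

All matrices are computed by vectorized neighbourhood scans on the ROI
bounding box; voxels outside the ROI never contribute.  Directional
families (GLCM, GLRLM) use the 13 unique 3-D directions at Chebyshev
distance 1 and aggregate by summing counts over directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .discretize import DiscreteROI

__all__ = ["TextureMatrix", "texture_matrix", "UNIQUE_DIRECTIONS", "ALL_NEIGHBORS"]

#: The 13 unique direction offsets (lexicographically positive half of the
#: 26-neighbourhood); the symmetric counterparts are implied.
UNIQUE_DIRECTIONS: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

#: All 26 neighbour offsets.
ALL_NEIGHBORS: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)

_FAMILY_AXES = {
    "glcm": "level x level",
    "glrlm": "level x run length",
    "glszm": "level x zone size",
    "ngtdm": "level -> (count, sum of absolute differences)",
    "gldm": "level x dependence",
}


@dataclass
class TextureMatrix:
    family: str
    matrix: np.ndarray
    axes: str
    normalized: bool = False

    def __post_init__(self) -> None:
        if (self.matrix < 0).any():
            raise ValueError("texture matrix entries must be non-negative")


def _shift_slices(shape, offset):
    src, dst = [], []
    for n, d in zip(shape, offset):
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    return tuple(src), tuple(dst)


def glcm_counts(roi: DiscreteROI, directions=UNIQUE_DIRECTIONS, symmetric: bool = True) -> np.ndarray:
    """Co-occurrence counts summed over directions (symmetrized by default)."""
    ng = roi.n_levels
    counts = np.zeros((ng, ng), dtype=np.float64)
    lev = roi.levels
    for off in directions:
        src, dst = _shift_slices(lev.shape, off)
        a, b = lev[src], lev[dst]
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        flat = (a[valid].astype(np.int64) - 1) * ng + (b[valid] - 1)
        counts += np.bincount(flat, minlength=ng * ng).reshape(ng, ng)
    if symmetric:
        counts = counts + counts.T
    return counts


def glrlm_counts(roi: DiscreteROI, directions=UNIQUE_DIRECTIONS) -> np.ndarray:
    """Run-length counts P(i, j): maximal collinear same-level segments.

    Runs are traced by flat-index stepping on a zero-padded level grid: the
    pad guarantees every run terminates at a level-0 voxel, so no bounds
    checks are needed.
    """
    lev = np.pad(roi.levels, 1)
    ng = roi.n_levels
    max_len = max(roi.levels.shape)
    counts = np.zeros((ng, max_len), dtype=np.float64)
    flat = lev.ravel()
    strides = (lev.shape[1] * lev.shape[2], lev.shape[2], 1)
    roi_idx = np.flatnonzero(flat > 0)
    vals = flat[roi_idx].astype(np.int64)
    for off in directions:
        step = off[0] * strides[0] + off[1] * strides[1] + off[2] * strides[2]
        starts_mask = flat[roi_idx - step] != vals
        starts = roi_idx[starts_mask]
        slev = vals[starts_mask]
        lengths = np.ones(len(starts), dtype=np.int64)
        cur = starts.copy()
        active = np.arange(len(starts))
        while len(active):
            nxt = cur[active] + step
            same = flat[nxt] == slev[active]
            cont = active[same]
            lengths[cont] += 1
            cur[cont] = nxt[same]
            active = cont
        counts += np.bincount((slev - 1) * max_len + (lengths - 1),
                              minlength=ng * max_len).reshape(ng, max_len)
    return counts


def glszm_counts(roi: DiscreteROI) -> np.ndarray:
    """Size-zone counts P(i, s): 26-connected equal-level components."""
    ng = roi.n_levels
    structure = np.ones((3, 3, 3), dtype=int)
    max_size = roi.n_voxels
    counts = np.zeros((ng, max_size), dtype=np.float64)
    for g in range(1, ng + 1):
        m = roi.levels == g
        if not m.any():
            continue
        lab, n = ndimage.label(m, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        counts[g - 1] += np.bincount(sizes - 1, minlength=max_size)[:max_size]
    return counts


def ngtdm_table(roi: DiscreteROI) -> np.ndarray:
    """NGTDM rows ``[n_i, s_i]`` per level i (26-neighbourhood mean differences)."""
    lev = roi.levels.astype(np.float64)
    in_roi = roi.mask.astype(np.float64)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nb_sum = ndimage.correlate(lev * in_roi, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.correlate(in_roi, kernel, mode="constant", cval=0.0)
    valid = roi.mask & (nb_cnt > 0)
    ng = roi.n_levels
    table = np.zeros((ng, 2), dtype=np.float64)
    if valid.any():
        levels_v = roi.levels[valid]
        diffs = np.abs(levels_v - nb_sum[valid] / nb_cnt[valid])
        table[:, 0] = np.bincount(levels_v - 1, minlength=ng)
        table[:, 1] = np.bincount(levels_v - 1, weights=diffs, minlength=ng)
    return table


def gldm_counts(roi: DiscreteROI, alpha: int = 0) -> np.ndarray:
    """Dependence counts P(i, d); d = 1 + #26-neighbours with |Δlevel| <= alpha."""
    lev = roi.levels
    dep = np.zeros(lev.shape, dtype=np.int64)
    for off in ALL_NEIGHBORS:
        src, dst = _shift_slices(lev.shape, off)
        contrib = np.zeros(lev.shape, dtype=np.int64)
        contrib[dst] = ((lev[src] > 0) & (np.abs(lev[dst].astype(np.int64) - lev[src]) <= alpha)).astype(np.int64)
        contrib[~roi.mask] = 0
        dep += contrib
    ng = roi.n_levels
    counts = np.zeros((ng, 27), dtype=np.float64)
    m = roi.mask
    flatidx = (lev[m].astype(np.int64) - 1) * 27 + dep[m]
    counts += np.bincount(flatidx, minlength=ng * 27).reshape(ng, 27)
    # trim trailing all-zero dependence columns; dependence index j = column + 1
    last = int(np.max(dep[m])) + 1
    return counts[:, :last]


def texture_matrix(roi: DiscreteROI, family: str, directions=None,
                   alpha: int = 0, normalize: bool | None = None) -> TextureMatrix:
    """Compute one texture matrix for the given family.

    GLCM is returned normalized to a probability matrix by default; the
    other families are returned as counts (their features use explicit
    normalizations).  ``directions`` restricts GLCM/GLRLM to a subset of
    the 13 unique directions.
    """
    family = family.lower()
    if family not in _FAMILY_AXES:
        raise ValueError(f"unknown texture family: {family!r}")
    dirs = UNIQUE_DIRECTIONS if directions is None else tuple(directions)
    if family == "glcm":
        m = glcm_counts(roi, dirs)
        if normalize is None or normalize:
            tot = m.sum()
            m = m / tot if tot > 0 else m
            return TextureMatrix("glcm", m, _FAMILY_AXES["glcm"], normalized=True)
        return TextureMatrix("glcm", m, _FAMILY_AXES["glcm"], normalized=False)
    if family == "glrlm":
        return TextureMatrix("glrlm", glrlm_counts(roi, dirs), _FAMILY_AXES["glrlm"])
    if family == "glszm":
        return TextureMatrix("glszm", glszm_counts(roi), _FAMILY_AXES["glszm"])
    if family == "ngtdm":
        return TextureMatrix("ngtdm", ngtdm_table(roi), _FAMILY_AXES["ngtdm"])
    return TextureMatrix("gldm", gldm_counts(roi, alpha=alpha), _FAMILY_AXES["gldm"])
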