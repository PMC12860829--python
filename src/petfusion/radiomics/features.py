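"""The 107-feature radiomics bank: per-family feature formulas.

Families and counts: firstorder (18), shape (14), glcm (24), glrlm (16),
glszm (16), ngtdm (5), gldm (14).  Formulas follow the standard IBSI /
fixed-bin-width conventions; degenerate ROIs (constant intensity, single
voxel) take their analytic limits where those are finite (variance-type
terms -> 0, correlation-type terms -> their perfect-dependence value) so
that constant regions never produce NaN columns — the stability filter of
the selection cascade removes the resulting zero-variance columns.
"""

from __future__ import annotations

import numpy as np

from ..volume import Volume3D
from .discretize import DiscreteROI, discretize
from .matrices import (glcm_counts, glrlm_counts, glszm_counts, gldm_counts,
                       ngtdm_table, UNIQUE_DIRECTIONS)

__all__ = ["FAMILIES", "FEATURE_NAMES", "compute_features", "feature_column_names"]

_EPS = np.finfo(np.float64).eps

FEATURE_NAMES: dict[str, tuple[str, ...]] = {
    "firstorder": (
        "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
        "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
        "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
        "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
    ),
    "shape": (
        "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
        "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
        "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
        "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
    ),
    "glcm": (
        "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
        "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
        "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
        "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
        "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
    ),
    "glrlm": (
        "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
        "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
        "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
        "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
        "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
        "LongRunHighGrayLevelEmphasis",
    ),
    "glszm": (
        "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
        "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
        "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
        "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
        "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
        "LargeAreaHighGrayLevelEmphasis",
    ),
    "ngtdm": ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength"),
    "gldm": (
        "SmallDependenceEmphasis", "LargeDependenceEmphasis",
        "GrayLevelNonUniformity", "DependenceNonUniformity",
        "DependenceNonUniformityNormalized", "GrayLevelVariance",
        "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
        "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
        "SmallDependenceHighGrayLevelEmphasis",
        "LargeDependenceLowGrayLevelEmphasis",
        "LargeDependenceHighGrayLevelEmphasis",
    ),
}

FAMILIES: tuple[str, ...] = tuple(FEATURE_NAMES)  # 18+14+24+16+16+5+14 = 107


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p))) if p.size else 0.0


# ---------------------------------------------------------------- firstorder

def firstorder_features(roi: DiscreteROI) -> dict[str, float]:
    x = roi.values
    n = x.size
    voxvol = float(np.prod(roi.spacing))
    mean = float(x.mean())
    var = float(x.var(ddof=0))
    sd = np.sqrt(var)
    p10, p25, p50, p75, p90 = (float(np.percentile(x, q)) for q in (10, 25, 50, 75, 90))
    inner = x[(x >= p10) & (x <= p90)]
    hist = np.bincount(roi.roi_levels - 1, minlength=roi.n_levels).astype(float)
    p = hist / n
    if sd > 0:
        z = (x - mean) / sd
        skew = float(np.mean(z ** 3))
        kurt = float(np.mean(z ** 4))
    else:
        skew, kurt = 0.0, 0.0
    return {
        "Energy": float(np.sum(x ** 2)),
        "TotalEnergy": voxvol * float(np.sum(x ** 2)),
        "Entropy": _entropy(p),
        "Minimum": float(x.min()),
        "10Percentile": p10,
        "90Percentile": p90,
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": p50,
        "InterquartileRange": p75 - p25,
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(inner - inner.mean()))) if inner.size else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(x ** 2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float(np.sum(p ** 2)),
    }


# --------------------------------------------------------------------- shape

def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    eroded = ndimage.binary_erosion(mask)
    return np.argwhere(mask & ~eroded)


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 400:
        try:
            from scipy.spatial import ConvexHull

            points = points[ConvexHull(points).vertices] if points.shape[1] == 3 else points
        except Exception:
            pass
    d2 = np.sum((points[:, None, :] - points[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def _max_inplane(points: np.ndarray, axis: int) -> float:
    """Max pairwise distance among surface voxels sharing a coordinate on ``axis``."""
    best = 0.0
    other = [a for a in range(3) if a != axis]
    for v in np.unique(points[:, axis]):
        sl = points[points[:, axis] == v][:, other]
        if len(sl) >= 2:
            d = _max_pairwise(sl)
            best = max(best, d)
    return best


def shape_features(mask: np.ndarray, spacing: tuple[float, float, float]) -> dict[str, float]:
    """Mesh- and eigenvalue-based 3-D shape descriptors of a binary ROI."""
    from skimage import measure

    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty ROI")
    spacing = tuple(float(s) for s in spacing)
    voxvol = float(np.prod(spacing))
    padded = np.pad(mask.astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    surface_area = float(measure.mesh_surface_area(verts, faces))
    tri = verts[faces]
    mesh_volume = float(abs(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2]))) / 6.0)
    sphericity = (36.0 * np.pi * mesh_volume ** 2) ** (1.0 / 3.0) / surface_area if surface_area > 0 else 0.0

    coords = np.argwhere(mask) * np.asarray(spacing)
    if len(coords) > 1:
        cov = np.cov(coords.T, ddof=0)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(e) for e in eig)
    elong = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
    flat = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0

    surf = _surface_voxels(mask)
    phys = surf * np.asarray(spacing)
    sp = np.asarray(spacing)
    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": n * voxvol,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume if mesh_volume > 0 else 0.0,
        "Sphericity": sphericity,
        "Maximum3DDiameter": _max_pairwise(phys),
        # max in-plane diameters; plane fixed along z (slice), y (column), x (row)
        "Maximum2DDiameterSlice": _max_inplane(surf, 2) if len(surf) else 0.0,
        "Maximum2DDiameterColumn": _max_inplane(surf, 1) if len(surf) else 0.0,
        "Maximum2DDiameterRow": _max_inplane(surf, 0) if len(surf) else 0.0,
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "LeastAxisLength": float(least),
        "Elongation": elong,
        "Flatness": flat,
    }


# ---------------------------------------------------------------------- glcm

def glcm_features(counts: np.ndarray) -> dict[str, float]:
    total = counts.sum()
    if total <= 0:
        # no voxel pairs (isolated voxels): treat as perfectly homogeneous
        counts, total = np.ones((1, 1)), 1.0
    p = counts / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = float(np.sum(i * px))
    muy = float(np.sum(i * py))
    sigx = float(np.sqrt(np.sum((i - mux) ** 2 * px)))
    sigy = float(np.sqrt(np.sum((i - muy) ** 2 * py)))

    # p_{x+y}(k), k = 2..2Ng ; p_{x-y}(k), k = 0..Ng-1
    ksum = np.zeros(2 * ng + 1)
    np.add.at(ksum, (ii + jj).astype(int).ravel(), p.ravel())
    kdiff = np.zeros(ng)
    np.add.at(kdiff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    ks = np.arange(2 * ng + 1, dtype=np.float64)
    kd = np.arange(ng, dtype=np.float64)

    diff_avg = float(np.sum(kd * kdiff))
    hxy = _entropy(p.ravel())
    hx = _entropy(px)
    hy = _entropy(py)
    pxpy = np.outer(px, py)
    nz = pxpy > 0
    hxy1 = float(-np.sum(p[nz] * np.log2(pxpy[nz])))
    hxy2 = float(-np.sum(pxpy[nz] * np.log2(pxpy[nz])))
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    if ng > 1 and (px > 0).sum() > 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            q = (p / px[:, None]) @ (p / py[None, :]).T
        q = np.nan_to_num(q)
        ev = np.sort(np.abs(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, ev[-2]))) if len(ev) > 1 else 1.0
    else:
        mcc = 1.0

    inv_var = float(np.sum(kdiff[1:] / kd[1:] ** 2)) if ng > 1 else 0.0
    corr = ((float(np.sum(ii * jj * p)) - mux * muy) / (sigx * sigy)) if sigx * sigy > 0 else 1.0
    return {
        "Autocorrelation": float(np.sum(ii * jj * p)),
        "JointAverage": mux,
        "ClusterProminence": float(np.sum((ii + jj - mux - muy) ** 4 * p)),
        "ClusterShade": float(np.sum((ii + jj - mux - muy) ** 3 * p)),
        "ClusterTendency": float(np.sum((ii + jj - mux - muy) ** 2 * p)),
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Correlation": corr,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": _entropy(kdiff),
        "DifferenceVariance": float(np.sum((kd - diff_avg) ** 2 * kdiff)),
        "JointEnergy": float(np.sum(p ** 2)),
        "JointEntropy": hxy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + ((ii - jj) / ng) ** 2))),
        "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "InverseVariance": inv_var,
        "MaximumProbability": float(p.max()),
        "SumAverage": float(np.sum(ks * ksum)),
        "SumEntropy": _entropy(ksum),
        "SumSquares": float(np.sum((ii - mux) ** 2 * p)),
        "MCC": mcc,
    }


# ------------------------------------------------- run/zone/dependence style

def _weighted_stats(P: np.ndarray):
    """Common level/size marginals for GLRLM/GLSZM/GLDM-style matrices."""
    N = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, P.shape[1] + 1, dtype=np.float64)[None, :]
    return N, i, j


def _rlm_style(P: np.ndarray, names: tuple[str, ...], n_voxels_total: float,
               percentage_key: str | None) -> dict[str, float]:
    N, i, j = _weighted_stats(P)
    if N <= 0:
        raise ValueError("empty texture matrix")
    p = P / N
    mu_i = float(np.sum(p * i))
    mu_j = float(np.sum(p * j))
    gl_marg = P.sum(axis=1)
    sz_marg = P.sum(axis=0)
    vals = {
        "short": float(np.sum(P / j ** 2) / N),
        "long": float(np.sum(P * j ** 2) / N),
        "gln": float(np.sum(gl_marg ** 2) / N),
        "glnn": float(np.sum(gl_marg ** 2) / N ** 2),
        "szn": float(np.sum(sz_marg ** 2) / N),
        "sznn": float(np.sum(sz_marg ** 2) / N ** 2),
        "pct": float(N / n_voxels_total) if n_voxels_total > 0 else 0.0,
        "glv": float(np.sum(p * (i - mu_i) ** 2)),
        "szv": float(np.sum(p * (j - mu_j) ** 2)),
        "entropy": _entropy(p.ravel()),
        "lgl": float(np.sum(P / i ** 2) / N),
        "hgl": float(np.sum(P * i ** 2) / N),
        "sl": float(np.sum(P / (i ** 2 * j ** 2)) / N),
        "sh": float(np.sum(P * i ** 2 / j ** 2) / N),
        "ll": float(np.sum(P * j ** 2 / i ** 2) / N),
        "lh": float(np.sum(P * i ** 2 * j ** 2) / N),
    }
    order = ("short", "long", "gln", "glnn", "szn", "sznn", "pct", "glv",
             "szv", "entropy", "lgl", "hgl", "sl", "sh", "ll", "lh")
    if percentage_key is None:  # GLDM: no GLNN/pct, different name order
        order = ("short", "long", "gln", "szn", "sznn", "glv", "szv",
                 "entropy", "lgl", "hgl", "sl", "sh", "ll", "lh")
    return dict(zip(names, (vals[k] for k in order)))


def glrlm_features(P: np.ndarray) -> dict[str, float]:
    # total voxel coverage = sum of j * P(i, j); robust to direction aggregation
    _, _, j = _weighted_stats(P)
    n_total = float(np.sum(P * j))
    return _rlm_style(P, FEATURE_NAMES["glrlm"], n_total, "RunPercentage")


def glszm_features(P: np.ndarray) -> dict[str, float]:
    _, _, j = _weighted_stats(P)
    n_total = float(np.sum(P * j))
    return _rlm_style(P, FEATURE_NAMES["glszm"], n_total, "ZonePercentage")


def gldm_features(P: np.ndarray) -> dict[str, float]:
    return _rlm_style(P, FEATURE_NAMES["gldm"], 0.0, None)


# --------------------------------------------------------------------- ngtdm

def ngtdm_features(table: np.ndarray) -> dict[str, float]:
    n_i = table[:, 0]
    s_i = table[:, 1]
    nvp = n_i.sum()
    if nvp <= 0:
        # no voxel has any neighbour: maximal coarseness, no texture change
        return {"Coarseness": 1e6, "Contrast": 0.0, "Busyness": 0.0,
                "Complexity": 0.0, "Strength": 0.0}
    p_i = n_i / nvp
    i = np.arange(1, len(n_i) + 1, dtype=np.float64)
    act = p_i > 0
    ngp = int(act.sum())
    ia, pa, sa = i[act], p_i[act], s_i[act]

    coarse_den = float(np.sum(p_i * s_i))
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6
    if ngp > 1:
        contrast = (float(np.sum(pa[:, None] * pa[None, :] * (ia[:, None] - ia[None, :]) ** 2))
                    / (ngp * (ngp - 1))) * float(s_i.sum()) / nvp
    else:
        contrast = 0.0
    busy_den = float(np.sum(np.abs((ia * pa)[:, None] - (ia * pa)[None, :])))
    busyness = coarse_den / busy_den if busy_den > 0 else 0.0
    pisi = pa * sa
    complexity = float(np.sum(np.abs(ia[:, None] - ia[None, :])
                              * (pisi[:, None] + pisi[None, :])
                              / (pa[:, None] + pa[None, :]))) / nvp
    s_sum = float(s_i.sum())
    strength = (float(np.sum((pa[:, None] + pa[None, :]) * (ia[:, None] - ia[None, :]) ** 2))
                / s_sum) if s_sum > 0 else 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ----------------------------------------------------------------- interface

def compute_features(volume: Volume3D, roi_mask: np.ndarray,
                     families: tuple[str, ...] = FAMILIES,
                     bin_width: float = 0.05,
                     shape_cache: dict[str, float] | None = None) -> dict[str, float]:
    """Compute the enabled feature families for one ROI.

    Returns a flat mapping ``"<family>_<feature>" -> value`` with exactly
    107 entries when all families are enabled.  ``shape_cache`` may supply
    precomputed shape features (they depend only on the ROI mask and
    spacing, so cohort extraction computes them once per region).
    """
    unknown = set(families) - set(FAMILIES)
    if unknown:
        raise ValueError(f"unknown families: {sorted(unknown)}")
    roi = discretize(volume, roi_mask, bin_width)
    out: dict[str, float] = {}
    for family in FAMILIES:
        if family not in families:
            continue
        if family == "firstorder":
            feats = firstorder_features(roi)
        elif family == "shape":
            feats = shape_cache if shape_cache is not None else \
                shape_features(np.asarray(roi_mask, bool), volume.spacing)
        elif family == "glcm":
            feats = glcm_features(glcm_counts(roi))
        elif family == "glrlm":
            feats = glrlm_features(glrlm_counts(roi))
        elif family == "glszm":
            feats = glszm_features(glszm_counts(roi))
        elif family == "ngtdm":
            feats = ngtdm_features(ngtdm_table(roi))
        else:
            feats = gldm_features(gldm_counts(roi))
        for name in FEATURE_NAMES[family]:
            out[f"{family}_{name}"] = feats[name]
    return out


def feature_column_names(region_names: list[str],
                         families: tuple[str, ...] = FAMILIES) -> list[str]:
    """Deterministic column order: regions by label id, families/features fixed."""
    cols = []
    for region in region_names:
        slug = region.replace(" ", "_")
        for family in FAMILIES:
            if family in families:
                for name in FEATURE_NAMES[family]:
                    cols.append(f"{slug}_{family}_{name}")
    return cols
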