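"""Synthetic parcellated FDG-PET phantom cohorts.

Real parkinsonian FDG-PET cohorts are private, so every downstream stage is
exercised on phantoms that emulate z-scorable SUVR volumes: a 20-region
parcellation (4 cortical slabs + 16 deep nuclei) inside an ellipsoidal
"brain", a positive baseline uptake per tissue class, disease-specific
multiplicative regional hypo-/hyper-metabolism, multiplicative voxel noise,
mild per-subject nuisance variability, and Gaussian smoothing that mimics
the scanner + spatial-normalization point-spread.

Default disease effect table (multiplicative uptake factors; regions not
listed have factor 1.0):

* MSA: putamen 0.85, pons 0.85, dentate nucleus 0.88
* PSP: caudate nucleus 0.85, thalamus 0.88, midbrain 0.85
* IPD: occipital cortex 0.92, putamen 1.05
* HC : all factors 1.0

The magnitudes are simulator parameters chosen so that desk-scale cohorts
are highly but not perfectly separable; they reflect the qualitative
metabolic patterns reported for these syndromes, not measured effect sizes.
A second-center cohort is emulated by a global intensity gain of 1.1,
voxel noise 0.12 and (by default) 10% smaller effect magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import gaussian_smooth
from .volume import AtlasLabels, Volume3D

__all__ = [
    "REGION_NAMES", "DiseaseEffect", "CohortSpec", "Cohort", "Subject",
    "build_parcellation", "brain_tissue_mask", "default_baseline",
    "default_effects", "simulate_subject", "simulate_cohort", "planted_tables",
]

#: The 20 parcellation regions, label ids 1..20 in this order.
REGION_NAMES: tuple[str, ...] = (
    "frontal cortex", "parietal cortex", "occipital cortex", "temporal cortex",
    "subthalamic nucleus", "nucleus accumbens", "ventral tegmental area",
    "locus coeruleus", "raphe nucleus", "dentate nucleus", "substantia nigra",
    "red nucleus", "thalamic basal nucleus", "caudate nucleus", "putamen",
    "globus pallidus", "thalamus", "medulla oblongata", "midbrain", "pons",
)

# Fractional geometry of the parcellation.  Cortical regions are slabs near
# the brain surface; the 16 nuclei are ellipsoids on a 4x2x2 interior
# lattice.  Fractions are of the grid extent per axis; the layout is
# disjoint by construction for any grid >= 32 voxels per axis.
_CORTICAL_SLABS: dict[str, tuple[tuple[float, float], ...]] = {
    # (x_lo,x_hi), (y_lo,y_hi), (z_lo,z_hi)
    "frontal cortex":   ((0.28, 0.72), (0.78, 0.92), (0.40, 0.68)),
    "parietal cortex":  ((0.28, 0.72), (0.30, 0.62), (0.80, 0.92)),
    "occipital cortex": ((0.28, 0.72), (0.08, 0.22), (0.40, 0.68)),
    "temporal cortex":  ((0.06, 0.18), (0.30, 0.65), (0.30, 0.55)),
}
_NUCLEUS_X = (0.29, 0.43, 0.57, 0.71)
_NUCLEUS_Y = (0.34, 0.56)
_NUCLEUS_Z = (0.33, 0.55)
_NUCLEUS_SEMIAXIS = 0.068  # fraction of grid extent, per axis


@dataclass(frozen=True)
class DiseaseEffect:
    """Multiplicative regional uptake factors for one diagnosis."""

    diagnosis: str
    factors: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.10  # voxelwise multiplicative Gaussian sd, pre-smoothing

    def __post_init__(self) -> None:
        unknown = set(self.factors) - set(REGION_NAMES)
        if unknown:
            raise ValueError(f"unknown regions in effect table: {sorted(unknown)}")
        if any(f <= 0 for f in self.factors.values()):
            raise ValueError("effect factors must be positive")

    def factor(self, region: str) -> float:
        return self.factors.get(region, 1.0)

    def scaled(self, scale: float) -> "DiseaseEffect":
        """Shrink/expand effect magnitudes: factor -> 1 + scale*(factor-1)."""
        return replace(self, factors={k: 1.0 + scale * (v - 1.0) for k, v in self.factors.items()})


def default_effects() -> dict[str, DiseaseEffect]:
    return {
        "HC": DiseaseEffect("HC", {}),
        "IPD": DiseaseEffect("IPD", {"occipital cortex": 0.92, "putamen": 1.05}),
        "MSA": DiseaseEffect("MSA", {"putamen": 0.85, "pons": 0.85, "dentate nucleus": 0.88}),
        "PSP": DiseaseEffect("PSP", {"caudate nucleus": 0.85, "thalamus": 0.88, "midbrain": 0.85}),
    }


def default_baseline() -> dict[str, float]:
    """Mean uptake per region plus background brain tissue (arbitrary units)."""
    base = {name: 1.25 for name in REGION_NAMES}
    for name in _CORTICAL_SLABS:
        base[name] = 1.15
    base["background"] = 1.0
    return base


def brain_tissue_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoidal brain support centred in the grid (semi-axes 0.46/axis)."""
    idx = np.indices(grid_shape, dtype=np.float64)
    r2 = np.zeros(grid_shape)
    for ax, n in enumerate(grid_shape):
        r2 += ((idx[ax] - 0.5 * (n - 1)) / (0.46 * n)) ** 2
    return r2 <= 1.0


def build_parcellation(grid_shape: tuple[int, int, int],
                       spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
                       seed: int = 0) -> AtlasLabels:
    """Place the 20 disjoint regions at fixed fractional positions.

    The seed applies a small global sub-region shift (<=1% of the grid per
    axis), which preserves disjointness; two calls with the same seed yield
    identical label grids.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    if any(n < 32 for n in grid_shape):
        raise ValueError(f"grid too small to place all regions disjointly: {grid_shape}")
    rng = np.random.default_rng(seed)
    shift = rng.uniform(-0.01, 0.01, size=3)
    labels = np.zeros(grid_shape, dtype=np.int16)
    registry: dict[int, str] = {}
    idx = np.indices(grid_shape, dtype=np.float64)
    frac = [idx[a] / grid_shape[a] for a in range(3)]

    label = 0
    for name, bounds in _CORTICAL_SLABS.items():
        label += 1
        registry[label] = name
        m = np.ones(grid_shape, dtype=bool)
        for ax, (lo, hi) in enumerate(bounds):
            m &= (frac[ax] >= lo + shift[ax]) & (frac[ax] < hi + shift[ax])
        if not m.any():
            raise ValueError(f"grid too small: region {name!r} is empty")
        labels[m] = label

    centers = [(cx, cy, cz) for cx in _NUCLEUS_X for cy in _NUCLEUS_Y for cz in _NUCLEUS_Z]
    nucleus_names = REGION_NAMES[4:]
    for name, (cx, cy, cz) in zip(nucleus_names, centers):
        label += 1
        registry[label] = name
        r2 = np.zeros(grid_shape)
        for ax, c in enumerate((cx, cy, cz)):
            r2 += ((frac[ax] - (c + shift[ax])) / _NUCLEUS_SEMIAXIS) ** 2
        m = r2 <= 1.0
        if not m.any():
            raise ValueError(f"grid too small: region {name!r} is empty")
        if (labels[m] != 0).any():
            raise ValueError("grid too small to place all regions disjointly")
        labels[m] = label

    return AtlasLabels(labels=labels, registry=registry)


def simulate_subject(atlas: AtlasLabels,
                     effect: DiseaseEffect,
                     baseline_map: dict[str, float],
                     seed: int,
                     spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
                     fwhm_mm: float = 10.0,
                     gain: float = 1.0,
                     subject_gain_sd: float = 0.03,
                     region_jitter_sd: float = 0.02) -> Volume3D:
    """Simulate one subject volume.

    voxel value = regional baseline x disease factor x per-subject regional
    jitter x (1 + voxel noise), scaled by the cohort gain and a per-subject
    global gain, then smoothed at ``fwhm_mm``.  The mask is the brain
    support (non-background voxels).  Deterministic given the seed.
    """
    if any(v <= 0 for v in baseline_map.values()):
        raise ValueError("baselines must be positive")
    if "background" not in baseline_map:
        raise ValueError("baseline_map must assign 'background' tissue uptake")
    rng = np.random.default_rng(seed)
    shape = atlas.labels.shape
    tissue = brain_tissue_mask(shape) | (atlas.labels > 0)

    data = np.zeros(shape, dtype=np.float64)
    data[tissue] = baseline_map["background"]
    for label, name in atlas.registry.items():
        m = atlas.labels == label
        jitter = 1.0 + region_jitter_sd * rng.standard_normal()
        data[m] = baseline_map[name] * effect.factor(name) * jitter

    subject_gain = 1.0 + subject_gain_sd * rng.standard_normal()
    data *= gain * subject_gain
    noise = 1.0 + effect.noise_sd * rng.standard_normal(shape)
    data[tissue] *= noise[tissue]
    vol = Volume3D(data=data, spacing=spacing, mask=tissue)
    if fwhm_mm > 0:
        vol = gaussian_smooth(vol, fwhm_mm)
    return vol


@dataclass(frozen=True)
class CohortSpec:
    """Per-class subject counts plus nuisance parameters for one cohort."""

    counts: dict[str, int]
    cohort_id: str = "A"
    grid_shape: tuple[int, int, int] = (79, 95, 69)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    fwhm_mm: float = 10.0
    gain: float = 1.0
    noise_sd: float = 0.10
    effect_scale: float = 1.0
    effects: dict[str, DiseaseEffect] | None = None
    baseline: dict[str, float] | None = None
    atlas_seed: int = 0

    def resolved_effects(self) -> dict[str, DiseaseEffect]:
        effects = dict(self.effects or default_effects())
        out = {}
        for diag, eff in effects.items():
            out[diag] = replace(eff.scaled(self.effect_scale), noise_sd=self.noise_sd)
        return out

    def second_center(self, cohort_id: str = "B", effect_scale: float = 0.9) -> "CohortSpec":
        """Emulated second-center cohort: gain x1.1, noisier, smaller effects."""
        return replace(self, cohort_id=cohort_id, gain=self.gain * 1.1,
                       noise_sd=0.12, effect_scale=self.effect_scale * effect_scale)


@dataclass
class Subject:
    subject_id: str
    volume: Volume3D
    diagnosis: str


@dataclass
class Cohort:
    subjects: list[Subject]
    cohort_id: str
    seed: int
    atlas: AtlasLabels

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(ids) != len(set(ids)):
            raise ValueError("subject ids must be unique")
        shapes = {s.volume.shape for s in self.subjects}
        if len(shapes) > 1:
            raise ValueError("all volumes must share one shape")

    @property
    def labels(self) -> list[str]:
        return [s.diagnosis for s in self.subjects]

    def manifest(self):
        import pandas as pd

        return pd.DataFrame({
            "subject_id": [s.subject_id for s in self.subjects],
            "diagnosis": self.labels,
            "cohort": self.cohort_id,
        })


def simulate_cohort(spec: CohortSpec, seed: int) -> Cohort:
    """Simulate a labeled cohort; per-subject seeds derive from the cohort seed."""
    if any(n <= 0 for n in spec.counts.values()):
        bad = [k for k, n in spec.counts.items() if n <= 0]
        raise ValueError(f"zero subjects requested for class(es): {bad}")
    atlas = build_parcellation(spec.grid_shape, spec.spacing, seed=spec.atlas_seed)
    effects = spec.resolved_effects()
    baseline = spec.baseline or default_baseline()
    rng = np.random.default_rng(seed)
    subjects: list[Subject] = []
    for diag in sorted(spec.counts):
        if diag not in effects:
            raise ValueError(f"no effect table entry for diagnosis {diag!r}")
        for i in range(spec.counts[diag]):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            vol = simulate_subject(atlas, effects[diag], baseline, seed=sub_seed,
                                   spacing=spec.spacing, fwhm_mm=spec.fwhm_mm,
                                   gain=spec.gain)
            subjects.append(Subject(f"{spec.cohort_id}_{diag}_{i:03d}", vol, diag))
    return Cohort(subjects=subjects, cohort_id=spec.cohort_id, seed=seed, atlas=atlas)


def planted_tables(n_subjects: int = 90, n_features: int = 50, n_informative: int = 5,
                   effect: float = 1.0, nuisance_shift: float = 0.2, seed: int = 0,
                   n_classes: int = 3):
    """Two small feature tables with a shared planted class signal.

    Emulates a pair of cohorts at the (post-normalization) feature-table
    level: ``n_informative`` columns carry class-dependent mean shifts with
    identical structure in both cohorts; the rest are pure noise.  The
    informative class-mean profiles are evenly spaced directions in the
    centered class-contrast space (scaled so the between-class standard
    deviation is ``effect``), so planted features are informative but not
    mutually collinear.  Cohort B adds a constant nuisance offset before
    each table is z-scored by its own statistics, mirroring the per-cohort
    harmonization applied to real feature tables.

    Returns ``(table_a, table_b, labels_a, labels_b, informative_names)``.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    names = [f"f{j:03d}" for j in range(n_features)]
    informative = names[:n_informative]

    # orthonormal basis of the centered contrast space (dim n_classes - 1)
    ones = np.ones((n_classes, 1)) / np.sqrt(n_classes)
    q, _ = np.linalg.qr(np.hstack([ones, rng.standard_normal((n_classes, n_classes - 1))]))
    basis = q[:, 1:]                                       # (C, C-1)
    theta0 = rng.uniform(0, np.pi)
    profiles = np.zeros((n_classes, n_informative))
    for i in range(n_informative):
        theta = theta0 + np.pi * i / n_informative
        direction = np.zeros(n_classes - 1)
        direction[0] = np.cos(theta)
        if n_classes > 2:
            direction[1] = np.sin(theta)
        m = basis @ direction
        profiles[:, i] = effect * m / m.std(ddof=0)

    def one(n, offset, rng):
        y = np.repeat(np.arange(n_classes), int(np.ceil(n / n_classes)))[:n]
        X = rng.standard_normal((n, n_features))
        X[:, :n_informative] += profiles[y]
        X += offset
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
        return pd.DataFrame(X, columns=names), y

    table_a, y_a = one(n_subjects, 0.0, rng)
    table_b, y_b = one(n_subjects, nuisance_shift, rng)
    return table_a, table_b, y_a, y_b, informative
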