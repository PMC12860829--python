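import numpy as np
import pytest

from petfusion.radiomics.discretize import DiscreteROI


def make_discrete_roi(levels: np.ndarray, spacing=(1.0, 1.0, 1.0), bin_width=1.0) -> DiscreteROI:
    """Wrap a synthetic integer level grid (0 = outside ROI) as a DiscreteROI."""
    levels = np.asarray(levels, dtype=np.int32)
    mask = levels > 0
    return DiscreteROI(levels=levels, mask=mask,
                       values=levels[mask].astype(np.float64),
                       n_levels=int(levels.max()), bin_width=bin_width, spacing=spacing)


def random_roi(rng: np.random.Generator, max_side: int = 6, max_levels: int = 5) -> np.ndarray:
    """Random small level grid with a random ROI support (never empty)."""
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    levels = rng.integers(1, max_levels + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < rng.uniform(0.3, 0.95)
    if not mask.any():
        mask.flat[rng.integers(mask.size)] = True
    levels[~mask] = 0
    if levels.max() == 0:
        levels.flat[np.flatnonzero(mask.ravel())[0]] = 1
    return levels


@pytest.fixture(scope="session")
def study_results():
    """Five seeded desk-scale end-to-end pipeline runs (the phantom study)."""
    from petfusion.config import PipelineConfig
    from petfusion.pipeline import run_pipeline

    return [run_pipeline(PipelineConfig(seed=seed)) for seed in (101, 102, 103, 104, 105)]


def _small_config():
    from dataclasses import replace

    from petfusion.config import PhantomConfig, PipelineConfig

    cfg = PipelineConfig(seed=42, phantom=PhantomConfig(
        n_train_per_class=12, n_test_per_class=6, n_cohort_b_per_class=12))
    return replace(cfg,
                   local_train=replace(cfg.local_train, epochs=3),
                   global_train=replace(cfg.global_train, epochs=5),
                   interpret=replace(cfg.interpret, n_permutations=40,
                                     instances_per_class=4, maps_per_class=4))


@pytest.fixture(scope="session")
def small_pipeline_pair():
    """The same small pipeline configuration run twice (determinism probe)."""
    from petfusion.pipeline import run_pipeline

    cfg = _small_config()
    return run_pipeline(cfg), run_pipeline(cfg)
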