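"""Pipeline configuration: flat key-value sections per module, JSON on disk.

Defaults follow the published analysis parameters where those are stated
(FWHM 10 mm; selection alpha = 0.5 then 1.0 with min-MSE lambda,
inter-cohort r > 0.6, redundancy r > 0.5; XGBoost softmax with learning
rate 0.025, gamma 0.1, max depth 6, L2 lambda 2) and desk-scale study sizes
everywhere the analysis scale is free (grid, network widths, cohort sizes),
so a default end-to-end run completes on one CPU.  ``paper_scale()`` gives
the full-size geometry (79x95x69 at 2 mm, 32/64/128-filter local channel,
78x96x66 Transformer input).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .localnet import LocalNetConfig, TrainConfig
from .globalnet import GlobalNetConfig
from .selection import SelectionConfig
from .fusion import ClassifierSpec

__all__ = ["PipelineConfig", "PhantomConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (40, 48, 35)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    n_train_per_class: int = 60
    n_test_per_class: int = 30
    n_cohort_b_per_class: int = 60
    fwhm_mm: float = 10.0
    noise_sd: float = 0.10
    cohort_b_gain: float = 1.1
    cohort_b_noise_sd: float = 0.12
    cohort_b_effect_scale: float = 1.0
    classes: tuple[str, ...] = ("IPD", "MSA", "PSP")
    atlas_seed: int = 0

    def __post_init__(self) -> None:
        if self.fwhm_mm < 0 or self.noise_sd < 0:
            raise ValueError("fwhm and noise sd must be non-negative")
        if min(self.n_train_per_class, self.n_test_per_class) < 1:
            raise ValueError("cohort sizes must be positive")


@dataclass(frozen=True)
class RadiomicsConfig:
    bin_width: float = 0.05
    families: tuple[str, ...] = ("firstorder", "shape", "glcm", "glrlm",
                                 "glszm", "ngtdm", "gldm")

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")


@dataclass(frozen=True)
class InterpretConfig:
    n_permutations: int = 120
    background_cap: int = 60
    instances_per_class: int = 12
    maps_per_class: int = 30
    cam_layer: str = "conv3"


@dataclass(frozen=True)
class PipelineConfig:
    seed: int
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    radiomics: RadiomicsConfig = field(default_factory=RadiomicsConfig)
    localnet: LocalNetConfig = field(default_factory=LocalNetConfig.desk_scale)
    globalnet: GlobalNetConfig = field(default_factory=GlobalNetConfig.desk_scale)
    #: the local channel is trained as a linear probe on calibrated conv
    #: features (head warmup only): end-to-end fine-tuning of the GAP pathway
    #: is unstable at desk scale and degrades both accuracy and attribution
    local_train: TrainConfig = field(default_factory=lambda: TrainConfig(
        epochs=0, head_warmup_epochs=60, patience=4))
    global_train: TrainConfig = field(default_factory=lambda: TrainConfig(epochs=25, patience=6))
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    interpret: InterpretConfig = field(default_factory=InterpretConfig)

    @staticmethod
    def paper_scale(seed: int) -> "PipelineConfig":
        return PipelineConfig(
            seed=seed,
            phantom=PhantomConfig(grid_shape=(79, 95, 69), spacing=(2.0, 2.0, 2.0)),
            localnet=LocalNetConfig(),
            globalnet=GlobalNetConfig(),
        )


_SECTIONS = {
    "phantom": PhantomConfig,
    "radiomics": RadiomicsConfig,
    "localnet": LocalNetConfig,
    "globalnet": GlobalNetConfig,
    "local_train": TrainConfig,
    "global_train": TrainConfig,
    "selection": SelectionConfig,
    "classifier": ClassifierSpec,
    "interpret": InterpretConfig,
}

_TUPLE_FIELDS = {"grid_shape", "spacing", "families", "classes", "input_shape", "layers"}


def _build_section(cls, payload: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - valid
    if unknown:
        raise KeyError(f"unknown keys in section {section!r}: {sorted(unknown)}")
    kwargs = {}
    for k, v in payload.items():
        if k in _TUPLE_FIELDS and isinstance(v, list):
            v = tuple(tuple(e) if isinstance(e, list) else e for e in v)
        kwargs[k] = v
    return cls(**kwargs)


def config_from_dict(payload: dict) -> PipelineConfig:
    payload = dict(payload)
    if "seed" not in payload:
        raise KeyError("config must specify a seed")
    seed = int(payload.pop("seed"))
    unknown = set(payload) - set(_SECTIONS)
    if unknown:
        raise KeyError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {name: _build_section(cls, payload[name], name)
              for name, cls in _SECTIONS.items() if name in payload}
    return PipelineConfig(seed=seed, **kwargs)


def load_config(path: str) -> PipelineConfig:
    """Load and validate a JSON pipeline configuration."""
    with open(path) as fh:
        payload = json.load(fh)
    return config_from_dict(payload)


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_to_jsonable(v) for v in obj]
    return obj


def config_to_dict(config: PipelineConfig) -> dict:
    return _to_jsonable(config)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
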