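"""Run configuration: one structured YAML file drives the whole pipeline.

Unknown keys are rejected (typos should fail loudly, not silently fall back
to defaults) and every constraint violation is reported with the offending
key path. The fully resolved configuration is echoed next to each run's
outputs so results remain reproducible from the artifacts alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import ConfigError, OctBrainError
from .frames import DEFAULT_SATURATION_THRESHOLD, DEFAULT_WINDOW, AugmentParams
from .model import ModelConfig
from .synthetic import AcquisitionSpec, DatasetSpec
from .training import TrainConfig


@dataclass(frozen=True)
class PreprocessConfig:
    window: int = DEFAULT_WINDOW
    stride: int = 1
    sat_threshold: float = DEFAULT_SATURATION_THRESHOLD
    register: bool = True

    def __post_init__(self) -> None:
        if self.window < 1 or self.stride < 1:
            raise ConfigError("window and stride must be >= 1")
        if not (0.0 < self.sat_threshold <= 1.0):
            raise ConfigError("sat_threshold must be in (0, 1]")


@dataclass(frozen=True)
class EvaluateConfig:
    n_folds: int = 5
    roc_grid_step: float = 0.01
    tsne_perplexity: float = 30.0
    n_cam_examples: int = 6

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if not (0.0 < self.roc_grid_step <= 0.5):
            raise ConfigError("roc_grid_step must be in (0, 0.5]")


@dataclass(frozen=True)
class RunConfig:
    master_seed: int = 0
    output_root: str = "runs"
    simulate: DatasetSpec = field(default_factory=DatasetSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    augment: AugmentParams = field(default_factory=AugmentParams)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)


_SECTION_TYPES = {
    "simulate": DatasetSpec,
    "preprocess": PreprocessConfig,
    "model": ModelConfig,
    "train": TrainConfig,
    "augment": AugmentParams,
    "evaluate": EvaluateConfig,
}

_TUPLE_FIELDS = {"input_shape", "stage_filters", "units_per_stage",
                 "attention_stages", "inclusion_radius_range"}


def _build_dataclass(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}; "
                          f"allowed: {sorted(names)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        key = f"{path}.{f.name}"
        if f.name == "acq":
            v = _build_dataclass(AcquisitionSpec, v, key)
        elif f.name in _TUPLE_FIELDS:
            v = tuple(v)
        kwargs[f.name] = v
    try:
        return cls(**kwargs)
    except ConfigError:
        raise
    except (OctBrainError, ValueError, TypeError) as e:
        raise ConfigError(f"{path}: {e}") from e


def parse_config(path) -> RunConfig:
    """Load and validate a YAML run configuration, applying defaults."""
    path = Path(path)
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as e:
        raise ConfigError(f"{path}: malformed YAML: {e}") from e
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - ({"master_seed", "output_root"} | set(_SECTION_TYPES))
    if unknown:
        raise ConfigError(f"{path}: unknown section(s) {sorted(unknown)}")
    kwargs = {}
    if "master_seed" in raw:
        kwargs["master_seed"] = int(raw["master_seed"])
    if "output_root" in raw:
        kwargs["output_root"] = str(raw["output_root"])
    for name, cls in _SECTION_TYPES.items():
        if name in raw:
            kwargs[name] = _build_dataclass(cls, raw[name], name)
    return RunConfig(**kwargs)


def resolved_dict(config: RunConfig) -> dict:
    """The fully resolved configuration as plain data (for echoing to disk)."""

    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: convert(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return list(obj)
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if hasattr(obj, "value") and not isinstance(obj, (int, float, str, bool)):
            return obj.value
        return obj

    return convert(config)


def write_resolved(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(resolved_dict(config), fh, sort_keys=True)
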