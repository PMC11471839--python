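"""Run configuration: one YAML file driving dataset, model, loss and training.

Every field has a default; unknown keys are rejected with the offending key
named, and ``load(save(config))`` round-trips exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ConfigurationError
from .model import DiscriminatorConfig, GeneratorConfig
from .neutro import LossConfig, PixelDomain
from .synthetic import IMAGE_KINDS, MASK_PATTERNS
from .training import TrainConfig

__all__ = ["DatasetConfig", "RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class DatasetConfig:
    n: int = 200
    image_kind: str = "gradient"
    mask_pattern: str = "mcar"
    height: int = 16
    width: int = 16
    rate_or_size: float | None = None

    def __post_init__(self) -> None:
        if self.image_kind not in IMAGE_KINDS:
            raise ConfigurationError(f"unknown image_kind {self.image_kind!r}")
        if self.mask_pattern not in MASK_PATTERNS:
            raise ConfigurationError(f"unknown mask_pattern {self.mask_pattern!r}")


@dataclass(frozen=True)
class RunConfig:
    domain: PixelDomain = field(default_factory=PixelDomain)
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    discriminator: DiscriminatorConfig = field(default_factory=DiscriminatorConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def train_config(self) -> TrainConfig:
        return dataclasses.replace(self.train, loss_config=self.loss)


_TUPLE_FIELDS = {"weight_kernel", "image_shape", "hidden_sizes"}


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigurationError(f"section {path or 'root'} must be a mapping")
    known = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            raise ConfigurationError(
                f"unknown configuration key {path + key!r}"
            )
        f = known[key]
        if dataclasses.is_dataclass(f.type) or key in _SECTIONS:
            kwargs[key] = _build(_SECTIONS[key], value, f"{path}{key}.")
        elif key in _TUPLE_FIELDS and value is not None:
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


_SECTIONS = {
    "domain": PixelDomain,
    "dataset": DatasetConfig,
    "loss": LossConfig,
    "generator": GeneratorConfig,
    "discriminator": DiscriminatorConfig,
    "train": TrainConfig,
}


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
                if f.name != "loss_config"}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def load_config(path) -> RunConfig:
    """Parse a YAML run configuration, applying defaults for absent keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = _build(RunConfig, data, "")
    return cfg


def save_config(config: RunConfig, path) -> None:
    """Write the full (defaulted) configuration back to YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)


def config_to_dict(config: RunConfig) -> dict:
    return _to_plain(config)
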