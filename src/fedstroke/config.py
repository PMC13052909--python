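"""Experiment configuration: a frozen-schema key/value tree.

Defaults follow the reference training setup: batch size 32, 10 local
epochs per client, Adam at learning rate 0.001, cross-entropy loss,
three clients holding equal splits. Unknown keys are rejected by name
so a typo never silently falls back to a default. Configurations load
from / dump to YAML and a resolved copy is written into every run
directory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict, is_dataclass

import yaml

__all__ = ["ExperimentConfig", "load_config", "save_config"]


class ConfigError(ValueError):
    pass


@dataclass
class DataConfig:
    n_samples: int = 600
    stroke_fraction: float = 0.38  # 950 / 2501, the CT collection mix
    missing_rate: float = 0.05
    image_height: int = 32
    image_width: int = 32
    separation: float = 0.5


@dataclass
class PreprocessConfig:
    impute_strategy: str = "mean"  # or "median"
    smote_enabled: bool = True
    smote_k: int = 5
    smote_ratio: float = 1.0


@dataclass
class ModelConfig:
    mlp_hidden: tuple = (32, 16)
    gru_hidden: int = 32
    transpose_scan: bool = False  # columns as timesteps instead of rows


@dataclass
class FederatedConfig:
    n_clients: int = 3
    rounds: int = 20  # maximum; early stopping may end sooner
    epochs_per_client: int = 10
    batch_size: int = 32
    lr: float = 0.001
    optimizer: str = "adam"
    weighting: str = "uniform"  # or "by-samples"
    partition_mode: str = "stratified"  # or "equal-random"
    val_fraction: float = 0.2  # global held-out validation split
    client_val_fraction: float = 0.2  # per-client local validation split
    tol: float = 1e-4
    patience: int = 3


@dataclass
class ExperimentConfig:
    data: DataConfig = field(default_factory=DataConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    federated: FederatedConfig = field(default_factory=FederatedConfig)
    seed: int = 0
    output_dir: str = "runs/default"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"]["mlp_hidden"] = list(self.model.mlp_hidden)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        cfg = cls()
        _merge(cfg, d, path="")
        cfg.validate()
        return cfg

    def validate(self) -> None:
        f = self.federated
        checks = [
            (self.data.n_samples > 0, "data.n_samples must be positive"),
            (0.0 <= self.data.stroke_fraction <= 1.0, "data.stroke_fraction in [0,1]"),
            (0.0 <= self.data.missing_rate < 1.0, "data.missing_rate in [0,1)"),
            (self.data.image_height >= 4 and self.data.image_width >= 4,
             "image dimensions must be >= 4"),
            (self.preprocess.impute_strategy in ("mean", "median"),
             "preprocess.impute_strategy must be mean or median"),
            (self.preprocess.smote_k >= 1, "preprocess.smote_k must be >= 1"),
            (0.0 < self.preprocess.smote_ratio <= 1.0,
             "preprocess.smote_ratio in (0,1]"),
            (f.n_clients >= 1, "federated.n_clients must be >= 1"),
            (f.rounds >= 0, "federated.rounds must be >= 0"),
            (f.epochs_per_client >= 0, "federated.epochs_per_client must be >= 0"),
            (f.batch_size >= 1, "federated.batch_size must be >= 1"),
            (f.lr > 0, "federated.lr must be positive"),
            (f.optimizer in ("adam", "sgd"), "federated.optimizer adam or sgd"),
            (f.weighting in ("uniform", "by-samples"),
             "federated.weighting uniform or by-samples"),
            (f.partition_mode in ("stratified", "equal-random"),
             "federated.partition_mode stratified or equal-random"),
            (0.0 < f.val_fraction < 1.0, "federated.val_fraction in (0,1)"),
            (0.0 < f.client_val_fraction < 1.0,
             "federated.client_val_fraction in (0,1)"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    def override(self, dotted: str, value) -> None:
        """Set e.g. ``federated.rounds`` from a dotted path string."""
        parts = dotted.split(".")
        obj = self
        for part in parts[:-1]:
            if not hasattr(obj, part):
                raise ConfigError(f"unknown config key {dotted!r}")
            obj = getattr(obj, part)
        leaf = parts[-1]
        if not is_dataclass(obj) or leaf not in {f.name for f in fields(obj)}:
            raise ConfigError(f"unknown config key {dotted!r}")
        current = getattr(obj, leaf)
        if isinstance(current, bool):
            value = str(value).lower() in ("1", "true", "yes")
        elif isinstance(current, int):
            value = int(value)
        elif isinstance(current, float):
            value = float(value)
        elif isinstance(current, tuple):
            value = tuple(int(v) for v in str(value).strip("()[]").split(",") if v)
        setattr(obj, leaf, value)


def _merge(obj, d: dict, path: str) -> None:
    valid = {f.name for f in fields(obj)}
    for key, val in d.items():
        full = f"{path}{key}"
        if key not in valid:
            raise ConfigError(f"unknown config key {full!r}")
        current = getattr(obj, key)
        if is_dataclass(current) and isinstance(val, dict):
            _merge(current, val, path=f"{full}.")
        elif is_dataclass(current):
            raise ConfigError(f"config key {full!r} expects a mapping")
        else:
            if isinstance(current, tuple) and isinstance(val, list):
                val = tuple(val)
            setattr(obj, key, val)


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return ExperimentConfig.from_dict(d)


def save_config(path, cfg: ExperimentConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
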