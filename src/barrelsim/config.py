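"""Configuration schema, validation and (de)serialization.

Configurations are YAML mappings validated against a strict schema:
unknown keys are rejected by name, defaults are filled in, and basic
unit sanity (positive durations, probabilities in [0, 1]) is enforced.
A round trip through :func:`save_config` / :func:`load_config` is
idempotent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

__all__ = [
    "ConfigError",
    "NetworkConfig",
    "SimulationBlock",
    "StateSweepBlock",
    "VariabilityBlock",
    "DeprivationBlock",
    "WhiskingImagingBlock",
    "ExperimentRecipe",
    "load_config",
    "save_config",
    "config_hash",
    "RECIPE_NAMES",
]

RECIPE_NAMES = ("state_sweep", "variability", "deprivation", "whisking_imaging")


class ConfigError(ValueError):
    """Invalid configuration: unknown key, bad unit or inconsistent value."""


@dataclass
class NetworkConfig:
    n_columns: int = 1
    scale: float = 1.0
    threshold_mode: str = "simple"
    compensate_weights: bool = True
    n_thal_per_column: int | None = None

    def validate(self) -> None:
        if self.n_columns < 1:
            raise ConfigError("network.n_columns must be >= 1")
        if not 0 < self.scale <= 2.0:
            raise ConfigError("network.scale must lie in (0, 2]")
        if self.threshold_mode not in ("simple", "adaptive", "fixed"):
            raise ConfigError(f"unknown network.threshold_mode {self.threshold_mode!r}")


@dataclass
class SimulationBlock:
    dt: float = 0.1
    duration_ms: float = 100.0

    def validate(self) -> None:
        if self.dt <= 0:
            raise ConfigError("simulation.dt must be > 0 ms")
        if self.duration_ms < self.dt:
            raise ConfigError("simulation.duration_ms must be >= dt")


@dataclass
class StateSweepBlock:
    states_mV: tuple = (-80.0, -70.0, -60.0)
    n_trials: int = 10

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ConfigError("state_sweep.n_trials must be >= 1")


@dataclass
class VariabilityBlock:
    n_trials: int = 20
    state_mV: float = -70.0

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ConfigError("variability.n_trials must be >= 1")


@dataclass
class DeprivationBlock:
    n_trials: int = 100
    variant: str = "repaired"
    pairing: str = "all_to_all"
    trial_duration_ms: float = 60.0

    def validate(self) -> None:
        if self.variant not in ("printed", "repaired"):
            raise ConfigError(f"unknown deprivation.variant {self.variant!r}")
        if self.pairing not in ("all_to_all", "nearest"):
            raise ConfigError(f"unknown deprivation.pairing {self.pairing!r}")


@dataclass
class WhiskingImagingBlock:
    duration_ms: float = 4000.0
    whisk_freq_hz: float = 8.0
    whisk_amp_deg: float = 15.0
    touch_times_ms: tuple = (1500.0, 2800.0)
    touch_curvature_amp: float = 0.05
    state_mV: float = -65.0

    def validate(self) -> None:
        if self.duration_ms <= 0:
            raise ConfigError("whisking_imaging.duration_ms must be > 0")
        for t in self.touch_times_ms:
            if not 0 <= t < self.duration_ms:
                raise ConfigError(f"touch time {t} ms outside the trace")


@dataclass
class ExperimentRecipe:
    """A complete, validated experiment description."""

    recipe: str = "state_sweep"
    seed: int = 0
    network: NetworkConfig = field(default_factory=NetworkConfig)
    simulation: SimulationBlock = field(default_factory=SimulationBlock)
    state_sweep: StateSweepBlock = field(default_factory=StateSweepBlock)
    variability: VariabilityBlock = field(default_factory=VariabilityBlock)
    deprivation: DeprivationBlock = field(default_factory=DeprivationBlock)
    whisking_imaging: WhiskingImagingBlock = field(default_factory=WhiskingImagingBlock)

    def validate(self) -> None:
        if self.recipe not in RECIPE_NAMES:
            raise ConfigError(
                f"unknown recipe {self.recipe!r}; expected one of {RECIPE_NAMES}"
            )
        for f in fields(self):
            v = getattr(self, f.name)
            if hasattr(v, "validate"):
                v.validate()


def _build(cls, data, path="config"):
    if not isinstance(data, dict):
        raise ConfigError(f"{path} must be a mapping")
    allowed = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {path}")
    kwargs = {}
    for name, f in allowed.items():
        if name not in data:
            continue
        val = data[name]
        if is_dataclass(f.type) if isinstance(f.type, type) else False:
            val = _build(f.type, val, f"{path}.{name}")
        elif isinstance(val, dict):
            # nested block declared via default_factory
            sub = type(getattr(cls(), name))
            val = _build(sub, val, f"{path}.{name}")
        elif isinstance(val, list):
            val = tuple(val)
        kwargs[name] = val
    return cls(**kwargs)


def load_config(path) -> ExperimentRecipe:
    """Load, default-fill and validate a YAML experiment config."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    data = yaml.safe_load(path.read_text()) or {}
    cfg = _build(ExperimentRecipe, data)
    cfg.validate()
    return cfg


def _to_plain(obj):
    if is_dataclass(obj):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(cfg: ExperimentRecipe, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=True))


def config_hash(cfg: ExperimentRecipe) -> str:
    """Stable short hash identifying a configuration."""
    blob = json.dumps(_to_plain(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
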