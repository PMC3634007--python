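"""Run configuration: YAML key/value text validated against a schema.

Defaults reproduce the canonical processing settings: 80 Hz sampling,
4th-order Butterworth at 0.2 Hz (15 Hz upper bound for the band-pass),
causal filtering, negative truncation ON for free-living human data and
OFF for the kinematics bench.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from typing import Optional

import yaml

from .errors import ConfigError

__all__ = ["MetricConfig", "SimulationConfig", "DailyConfig", "RunConfig", "load_config"]


@dataclass
class MetricConfig:
    name: str = "ENMO"
    order: int = 4
    cutoff_low_hz: float = 0.2
    cutoff_high_hz: float = 15.0
    zero_phase: bool = False
    truncate_negatives: bool = True

    def validate(self) -> None:
        from .metrics import METRIC_NAMES

        if self.name not in METRIC_NAMES:
            raise ConfigError(f"metric.name must be one of {METRIC_NAMES}")
        if self.order < 1:
            raise ConfigError("filter.order must be >= 1")
        if self.cutoff_low_hz <= 0 or self.cutoff_high_hz <= self.cutoff_low_hz:
            raise ConfigError("require 0 < cutoff_low_hz < cutoff_high_hz")


@dataclass
class SimulationConfig:
    noise_sd_g: float = 0.0
    seed: Optional[int] = None
    fs: float = 80.0
    duration_s: float = 180.0

    def validate(self) -> None:
        if self.noise_sd_g < 0:
            raise ConfigError("simulation.noise_sd_g must be >= 0")
        if self.noise_sd_g > 0 and self.seed is None:
            raise ConfigError("simulation.seed is required when noise_sd_g > 0")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ConfigError("simulation.fs and duration_s must be positive")


@dataclass
class DailyConfig:
    block_length_min: int = 15
    epoch_length_s: int = 60
    nonwear_window_min: int = 60
    nonwear_sd_threshold_g: float = 0.013
    nonwear_min_axes: int = 2
    clipping_range_g: float = 6.0
    clipping_frac_threshold: float = 0.01

    def validate(self) -> None:
        if self.block_length_min * 60 % self.epoch_length_s:
            raise ConfigError("block length must be a whole number of epochs")
        if self.nonwear_sd_threshold_g <= 0:
            raise ConfigError("nonwear_sd_threshold_g must be positive")


@dataclass
class RunConfig:
    metric: MetricConfig = field(default_factory=MetricConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    daily: DailyConfig = field(default_factory=DailyConfig)
    out_dir: str = "."

    def validate(self) -> None:
        self.metric.validate()
        self.simulation.validate()
        self.daily.validate()

    def to_dict(self) -> dict:
        return asdict(self)


def _build(section_cls, mapping: dict, prefix: str):
    known = {f.name for f in fields(section_cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"unknown key(s) under {prefix!r}: {sorted(unknown)}")
    return section_cls(**mapping)


def load_config(path: str) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {"metric", "simulation", "daily", "out_dir"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown top-level key(s): {sorted(unknown)}")
    cfg = RunConfig(
        metric=_build(MetricConfig, raw.get("metric", {}) or {}, "metric"),
        simulation=_build(SimulationConfig, raw.get("simulation", {}) or {}, "simulation"),
        daily=_build(DailyConfig, raw.get("daily", {}) or {}, "daily"),
        out_dir=raw.get("out_dir", "."),
    )
    cfg.validate()
    return cfg
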