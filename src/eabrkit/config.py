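"""Study configuration: one YAML file fully determines a run."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import yaml

from .synthdata import DEFAULT_CHARGE_LEVELS_NC

__all__ = ["StudyConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


DEFAULT_SHAPES = ["rec", "ramp_up", "ramp_down", "ramp_long"]
DEFAULT_POLARITIES = ["anodic_first", "cathodic_first"]


@dataclass
class StudyConfig:
    """All knobs of a simulated study and its analysis.

    Sections ``generator``, ``preprocess``, ``quantify``, ``fit`` and
    ``model`` are free dictionaries of overrides; absent keys fall back
    to package defaults.  ``model: null`` skips the filter-model stage.
    """

    seed: int = 0
    shapes: list = field(default_factory=lambda: list(DEFAULT_SHAPES))
    polarities: list = field(default_factory=lambda: list(DEFAULT_POLARITIES))
    phase_durations_us: list = field(default_factory=lambda: [25.0])
    interphase_gap_us: float = 10.0
    charge_levels_nc: list = field(
        default_factory=lambda: list(DEFAULT_CHARGE_LEVELS_NC)
    )
    generator: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    quantify: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    model: dict | None = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.shapes:
            raise ConfigError("shapes must be non-empty")
        if not self.polarities:
            raise ConfigError("polarities must be non-empty")
        if not self.charge_levels_nc:
            raise ConfigError("charge_levels_nc must be non-empty")
        if sorted(self.charge_levels_nc) != list(self.charge_levels_nc):
            raise ConfigError("charge_levels_nc must be increasing")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
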