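"""YAML/JSON configuration: world, cohort, protocol and stats sections.

Every report produced by the pipeline echoes the fully resolved
configuration for provenance.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .geometry import WorldConfig
from .protocol import ProtocolSpec
from .subject_model import CohortSpec

__all__ = ["StatsConfig", "Config", "load_config", "config_dict"]


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    holm_adjust: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class Config:
    world: WorldConfig = field(default_factory=WorldConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    stats: StatsConfig = field(default_factory=StatsConfig)


_SECTIONS = {
    "world": WorldConfig,
    "cohort": CohortSpec,
    "protocol": ProtocolSpec,
    "stats": StatsConfig,
}


def _build(cls, mapping: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} option(s): {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in mapping.items()
    }
    return cls(**coerced)


def load_config(path: str | Path | None) -> Config:
    """Load a YAML (or JSON) config; missing sections fall back to defaults."""
    if path is None:
        return Config()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    kwargs = {
        name: _build(cls, raw.get(name, {}) or {}) for name, cls in _SECTIONS.items()
    }
    return Config(**kwargs)


def config_dict(config: Config) -> dict:
    """JSON-serializable echo of the full configuration."""
    return json.loads(json.dumps(asdict(config)))
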