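"""YAML configuration mapped onto the package's dataclasses.

A config file has up to five sections — ``io``, ``graph``, ``model``,
``segment`` and ``metrics`` — each holding keyword overrides for the
corresponding defaults. Missing sections and keys fall back to the
documented defaults, so an empty file is a valid config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .graph import GraphConfig
from .model import ModelConfig
from .segment import AssignmentPolicy


@dataclass(frozen=True)
class IoConfig:
    min_quality: float = 20.0
    min_counts: int = 5
    fold_change: float = 2.0


@dataclass(frozen=True)
class MetricsConfig:
    codetect_max: float = 0.01
    min_counts: int = 5


@dataclass
class Config:
    io: IoConfig = field(default_factory=IoConfig)
    graph: GraphConfig = field(default_factory=GraphConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    segment: AssignmentPolicy = field(default_factory=AssignmentPolicy)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)


_SECTIONS = {
    "io": IoConfig,
    "graph": GraphConfig,
    "model": ModelConfig,
    "segment": AssignmentPolicy,
    "metrics": MetricsConfig,
}


def load_config(path: str | Path | None = None) -> Config:
    """Load a config file; ``None`` yields all defaults."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {})
        if section is None:
            section = {}
        unknown = set(section) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown keys in config section {name!r}: {sorted(unknown)}")
        kwargs[name] = cls(**section)
    return Config(**kwargs)
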