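"""Pipeline configuration: one YAML schema shared by every subcommand.

Unknown keys are rejected so that typos fail loudly rather than silently
falling back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .counting import CountingConfig
from .evaluation import EvaluationConfig
from .simulate import NoiseConfig, SimulationConfig
from .tracking import TrackerConfig


class ConfigError(ValueError):
    """A configuration file violates the schema."""


_TUPLE_FIELDS = {"frame_size", "entry_zone", "confidence_range_true", "confidence_range_false"}
_ARRAY_FIELDS = {"confusion_matrix", "map_iou_grid", "recall_grid"}


def _build(cls, data: dict[str, Any], section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys in [{section}]: {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        if k in _TUPLE_FIELDS and isinstance(v, (list, tuple)):
            v = tuple(v)
        elif k in _ARRAY_FIELDS:
            v = np.asarray(v, dtype=float)
        kwargs[k] = v
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [{section}] configuration: {exc}") from exc


@dataclass
class OccupancySettings:
    segment_seconds: float = 5.0
    duration_mode: str = "indicator"
    presence_threshold: float = 0.5
    grouping: str = "cam_icu_binary"
    max_offset_minutes: float = 30.0
    assessments_path: str | None = None


@dataclass
class PipelineConfig:
    """Nested configuration for the end-to-end pipeline."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    counting: CountingConfig = field(default_factory=CountingConfig)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    occupancy: OccupancySettings = field(default_factory=OccupancySettings)
    seed: int = 0
    output_dir: str = "icucount_output"

    _SECTIONS = {
        "simulation": SimulationConfig,
        "noise": NoiseConfig,
        "counting": CountingConfig,
        "tracker": TrackerConfig,
        "evaluation": EvaluationConfig,
        "occupancy": OccupancySettings,
    }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data or {})
        unknown = set(data) - set(cls._SECTIONS) - {"seed", "output_dir"}
        if unknown:
            raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for section, section_cls in cls._SECTIONS.items():
            if section in data:
                sub = data[section]
                if not isinstance(sub, dict):
                    raise ConfigError(f"[{section}] must be a mapping")
                kwargs[section] = _build(section_cls, sub, section)
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        if "output_dir" in data:
            kwargs["output_dir"] = str(data["output_dir"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError("top level of the config file must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, tuple):
                return list(obj)
            return obj
        return clean(d)
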