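"""Run configuration: one serializable object covering every stage.

A :class:`RunConfig` round-trips losslessly through YAML; unknown keys are
rejected with the offending name so typos never silently fall back to
defaults. The configuration hash embedded in output artifacts is the SHA-256
of the canonical YAML serialization.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .detect import DetectorConfig

__all__ = ["SuppressionConfig", "EvaluationConfig", "SpO2Config", "RunConfig"]


@dataclass(frozen=True)
class SuppressionConfig:
    """Baseline-suppression settings; ``level=None`` means the deepest level."""

    wavelet: str = "sym8"
    level: int | None = None
    block_size: int = 1024


@dataclass(frozen=True)
class EvaluationConfig:
    tolerance_ms: float = 150.0


@dataclass(frozen=True)
class SpO2Config:
    """Calibration coefficients have no defaults; they are device-specific."""

    A: float | None = None
    B: float | None = None
    form: str = "linear"


@dataclass(frozen=True)
class RunConfig:
    suppression: SuppressionConfig = field(default_factory=SuppressionConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    spo2: SpO2Config = field(default_factory=SpO2Config)
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["detector"]["levels_used"] = list(self.detector.levels_used)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        kwargs = {}
        sections = {
            "suppression": SuppressionConfig,
            "detector": DetectorConfig,
            "evaluation": EvaluationConfig,
            "spo2": SpO2Config,
        }
        for name, section_cls in sections.items():
            if name in data:
                kwargs[name] = _build_section(section_cls, data.pop(name), name)
        if "log_level" in data:
            kwargs["log_level"] = str(data.pop("log_level"))
        if data:
            raise ValueError(f"unknown configuration keys: {sorted(data)}")
        return cls(**kwargs)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        text = Path(source).read_text() if isinstance(source, Path) else source
        return cls.from_dict(yaml.safe_load(text) or {})

    @classmethod
    def from_yaml_file(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        """SHA-256 of the canonical YAML serialization (provenance tag)."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _build_section(section_cls, values: dict, name: str):
    values = dict(values or {})
    fields = {f.name for f in dataclasses.fields(section_cls)}
    unknown = set(values) - fields
    if unknown:
        raise ValueError(f"unknown configuration keys in '{name}': {sorted(unknown)}")
    if section_cls is DetectorConfig and "levels_used" in values:
        values["levels_used"] = tuple(values["levels_used"])
    return section_cls(**values)
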