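"""Run configuration: a validated YAML schema over the component configs."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .beats import FrontEndConfig
from .detector import DetectorConfig

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for unknown keys or invalid values in a config file."""


@dataclass(frozen=True)
class EvaluationOptions:
    af_fraction_threshold: float = 0.5
    exclude_records: tuple = ("07859",)

    def __post_init__(self) -> None:
        if not 0 < self.af_fraction_threshold <= 1:
            raise ConfigError("af_fraction_threshold must lie in (0, 1]")
        object.__setattr__(self, "exclude_records", tuple(self.exclude_records))


@dataclass(frozen=True)
class RunConfig:
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    frontend: FrontEndConfig = field(default_factory=FrontEndConfig)
    evaluation: EvaluationOptions = field(default_factory=EvaluationOptions)
    seed: int = 0

    def digest(self) -> str:
        """Short stable hash of the full configuration, for log lines."""
        parts = []
        for section in (self.detector, self.frontend, self.evaluation):
            parts.append(repr(dataclasses.asdict(section)))
        parts.append(str(self.seed))
        return hashlib.blake2b("|".join(parts).encode(), digest_size=6).hexdigest()


def _build(cls, mapping: dict, section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in '{section}': {', '.join(sorted(unknown))}"
        )
    try:
        return cls(**mapping)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{section}' config: {exc}") from None


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected.

    Schema: top-level keys ``detector``, ``frontend``, ``evaluation``,
    ``seed``.  ``overrides`` maps dotted keys (e.g. ``detector.af_threshold``)
    to values applied after the file.
    """
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data = raw
    unknown = set(data) - {"detector", "frontend", "evaluation", "seed"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")
    sections = {
        "detector": dict(data.get("detector") or {}),
        "frontend": dict(data.get("frontend") or {}),
        "evaluation": dict(data.get("evaluation") or {}),
    }
    seed = int(data.get("seed", 0))
    for dotted, value in (overrides or {}).items():
        section, _, key = dotted.partition(".")
        if section == "seed" and not key:
            seed = int(value)
        elif section in sections and key:
            sections[section][key] = value
        else:
            raise ConfigError(f"unknown override {dotted!r}")
    return RunConfig(
        detector=_build(DetectorConfig, sections["detector"], "detector"),
        frontend=_build(FrontEndConfig, sections["frontend"], "frontend"),
        evaluation=_build(EvaluationOptions, sections["evaluation"], "evaluation"),
        seed=seed,
    )
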