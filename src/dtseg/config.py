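"""YAML run configuration: validated TrainSpec / NetworkSpec / PhantomSpec.

An empty (or missing-section) config yields the full-scale defaults
(232x232x32 crop, lr0 1e-4, 110 epochs, widths 16-128).  Unknown keys are
rejected by name so typos never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .networks import NetworkSpec
from .synthetic import PhantomSpec
from .training import TrainSpec


class ConfigError(ValueError):
    pass


_SECTIONS = {"train": TrainSpec, "network": NetworkSpec, "phantom": PhantomSpec}


@dataclass
class RunConfig:
    train: TrainSpec = field(default_factory=TrainSpec)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    paths: dict[str, str] = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        self.train.check_against(self.network)
        return self


def _build(cls, section: str, mapping: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(mapping) - set(fields)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section '{section}': {sorted(unknown)}"
        )
    kwargs = {}
    for key, value in mapping.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section '{section}': {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config; see :class:`RunConfig`."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - {"paths"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name) or {}
        if not isinstance(section, dict):
            raise ConfigError(f"section '{name}' must be a mapping")
        kwargs[name] = _build(cls, name, section)
    paths = raw.get("paths") or {}
    if not isinstance(paths, dict):
        raise ConfigError("section 'paths' must be a mapping")
    return RunConfig(paths={k: str(v) for k, v in paths.items()}, **kwargs).validate()
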