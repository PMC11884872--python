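"""Structured run configuration: defaults, YAML loading, provenance echo.

A run configuration bundles the task geometry (:class:`TrialConfig`), the
tone map (:class:`SonificationConfig`), the cohort design and planted
learning dynamics, the camera calibration, and a master seed. Config files
are flat YAML sections; unknown sections or keys are rejected by name, and
every pipeline output directory receives a copy of the fully resolved
effective config for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .engine import TrialConfig
from .pose import Calibration
from .simulate import CohortDesign, LearningParams
from .sonification import SonificationConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config", "config_to_dict"]


class ConfigError(ValueError):
    """Unknown key, bad type or invalid value in a config file."""


@dataclass
class RunConfig:
    trial: TrialConfig = field(default_factory=TrialConfig)
    sonification: SonificationConfig = field(default_factory=SonificationConfig)
    design: CohortDesign = field(default_factory=CohortDesign)
    learning: LearningParams = field(default_factory=LearningParams)
    calibration: Calibration = field(default_factory=Calibration)
    seed: int = 0


_SECTIONS = {
    "trial": TrialConfig,
    "sonification": SonificationConfig,
    "design": CohortDesign,
    "learning": LearningParams,
    "calibration": Calibration,
}


def _coerce(section: str, name: str, ftype: Any, value: Any) -> Any:
    try:
        if ftype is float or ftype == "float":
            if isinstance(value, bool):
                raise TypeError
            return float(value)
        if ftype is int or ftype == "int":
            if isinstance(value, bool) or (isinstance(value, float) and value != int(value)):
                raise TypeError
            return int(value)
        if ftype is str or ftype == "str":
            if not isinstance(value, str):
                raise TypeError
            return value
        if isinstance(value, (list, tuple)):
            return tuple(value)
        return value
    except (TypeError, ValueError):
        raise ConfigError(
            f"config key {section}.{name}: cannot interpret {value!r} as {ftype}"
        ) from None


def _build_section(section: str, cls: type, data: dict) -> Any:
    if not isinstance(data, dict):
        raise ConfigError(f"config section {section!r} must be a mapping")
    known = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            raise ConfigError(f"unknown config key {section}.{key}")
        kwargs[key] = _coerce(section, key, known[key].type, value)
    try:
        return cls(**kwargs)
    except ValueError as exc:
        raise ConfigError(f"invalid value in section {section!r}: {exc}") from exc


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run config; missing keys fall back to defaults.

    An empty (or absent) file yields the full default configuration. Unknown
    sections/keys and out-of-range values raise :class:`ConfigError` naming
    the offending key.
    """
    data: dict = {}
    if path is not None:
        raw = Path(path).read_text(encoding="utf-8")
        loaded = yaml.safe_load(raw)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping of sections")
        data = loaded
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key == "seed":
            kwargs["seed"] = _coerce("", "seed", int, value)
        elif key in _SECTIONS:
            kwargs[key] = _build_section(key, _SECTIONS[key], value or {})
        else:
            raise ConfigError(f"unknown config section or key {key!r}")
    return RunConfig(**kwargs)


def config_to_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    # YAML-friendly: tuples to lists.
    d["design"]["groups"] = list(d["design"]["groups"])
    return d


def dump_config(cfg: RunConfig, path: str | Path) -> Path:
    """Write the fully resolved effective config as YAML."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)
    return path
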