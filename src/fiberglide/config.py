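"""Experiment configuration: defaults, validation, YAML round-tripping.

A single YAML (or JSON) file describes a complete experiment: fiber
geometry, per-channel motility parameters, acquisition schedule, photon
model, seeds and detection settings.  Every field has a documented
default; validation errors name the offending key.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .acquisition import PhotonModel, ShutterSchedule
from .decay import SpeedCalibration
from .simulator import FiberGeometry, MotilityParams

__all__ = ["ExperimentConfig", "ConfigError", "load_config", "save_config"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Configuration is invalid; the message names the offending key."""


@dataclass
class ExperimentConfig:
    """Fully resolved configuration of one (possibly two-channel) experiment."""

    geometry: FiberGeometry = field(default_factory=FiberGeometry)
    schedule: ShutterSchedule = field(default_factory=lambda: ShutterSchedule(channels=("A", "B")))
    # dual-fluorophore detection runs dimmer per channel than single-channel
    # speed calibration (weaker dyes, filter losses): photon-noise-limited
    # regime in which the per-window KS comparison is well calibrated
    photon_model: PhotonModel = field(
        default_factory=lambda: PhotonModel(counts_per_microtubule=0.08, background_mean=360.0)
    )
    channel_params: dict = field(default_factory=dict)
    calibration: SpeedCalibration | None = None
    n_tips: int = 500
    duration: float = 900.0
    background_duration: float = 120.0
    seed: int = 0
    alpha: float = 0.05
    bundling_min_r2: float = 0.8
    bundling_max_plateau: float = 0.8
    control_channel: str | None = None
    measure_channel: str | None = None

    def __post_init__(self) -> None:
        if self.control_channel is None:
            self.control_channel = self.schedule.channels[0]
        if self.measure_channel is None:
            self.measure_channel = self.schedule.channels[-1]
        for label in self.schedule.channels:
            self.channel_params.setdefault(label, MotilityParams())
        if self.n_tips < 1:
            raise ConfigError("n_tips must be >= 1")
        if self.duration <= 0:
            raise ConfigError("duration must be > 0")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")
        for name in ("control_channel", "measure_channel"):
            label = getattr(self, name)
            if label not in self.schedule.channels:
                raise ConfigError(f"{name}: {label!r} is not a scheduled channel")


_SECTION_TYPES = {
    "geometry": FiberGeometry,
    "schedule": ShutterSchedule,
    "photon_model": PhotonModel,
}


def _build_section(name: str, cls, data: dict):
    if not isinstance(data, dict):
        raise ConfigError(f"{name}: expected a mapping")
    valid = {f.name for f in dataclasses.fields(cls)}
    for key in data:
        if key not in valid:
            raise ConfigError(f"{name}.{key}: unknown key")
    if cls is ShutterSchedule and "channels" in data:
        data = {**data, "channels": tuple(data["channels"])}
    try:
        return cls(**data)
    except (ValueError, TypeError) as err:
        bad = _first_bad_key(cls, data)
        raise ConfigError(f"{name}.{bad}: {err}") from err


def _first_bad_key(cls, data: dict) -> str:
    """Bisect which single key makes the section invalid (best effort)."""
    for key, value in data.items():
        try:
            cls(**{key: value} if key != "channels" else {key: tuple(value)})
        except (ValueError, TypeError):
            return key
    return "/".join(data) or "?"


def load_config(path) -> ExperimentConfig:
    """Load, default-fill and validate an experiment configuration file."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("top level: expected a mapping")
    return config_from_dict(data)


def config_from_dict(data: dict) -> ExperimentConfig:
    known = {
        "geometry",
        "schedule",
        "photon_model",
        "channels",
        "calibration",
        "n_tips",
        "duration",
        "background_duration",
        "seed",
        "alpha",
        "bundling_min_r2",
        "bundling_max_plateau",
        "control_channel",
        "measure_channel",
    }
    for key in data:
        if key not in known:
            raise ConfigError(f"{key}: unknown key")

    sections = {}
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            sections[name] = _build_section(name, cls, data[name])
            logger.debug("config: %s taken from file", name)
        else:
            logger.debug("config: %s using package defaults", name)
    schedule = sections.get("schedule", ShutterSchedule(channels=("A", "B")))

    channel_params = {}
    for label, sub in (data.get("channels") or {}).items():
        if label not in schedule.channels:
            raise ConfigError(f"channels.{label}: not in schedule.channels")
        channel_params[label] = _build_section(f"channels.{label}", MotilityParams, sub or {})

    calibration = None
    if data.get("calibration") is not None:
        cal = data["calibration"]
        if not isinstance(cal, dict) or "H" not in cal:
            raise ConfigError("calibration.H: required")
        try:
            calibration = SpeedCalibration(
                H=float(cal["H"]),
                r=float(cal.get("r", sections.get("geometry", FiberGeometry()).core_radius)),
            )
        except ValueError as err:
            raise ConfigError(f"calibration: {err}") from err

    scalars = {
        k: data[k]
        for k in (
            "n_tips",
            "duration",
            "background_duration",
            "seed",
            "alpha",
            "bundling_min_r2",
            "bundling_max_plateau",
            "control_channel",
            "measure_channel",
        )
        if k in data
    }
    kwargs = dict(sections)
    kwargs["schedule"] = schedule
    return ExperimentConfig(
        channel_params=channel_params, calibration=calibration, **kwargs, **scalars
    )


def config_to_dict(config: ExperimentConfig) -> dict:
    out = {
        "geometry": dataclasses.asdict(config.geometry),
        "schedule": {**dataclasses.asdict(config.schedule), "channels": list(config.schedule.channels)},
        "photon_model": dataclasses.asdict(config.photon_model),
        "channels": {
            label: dataclasses.asdict(p) for label, p in config.channel_params.items()
        },
        "n_tips": config.n_tips,
        "duration": config.duration,
        "background_duration": config.background_duration,
        "seed": config.seed,
        "alpha": config.alpha,
        "bundling_min_r2": config.bundling_min_r2,
        "bundling_max_plateau": config.bundling_max_plateau,
        "control_channel": config.control_channel,
        "measure_channel": config.measure_channel,
    }
    if config.calibration is not None:
        out["calibration"] = {"H": config.calibration.H, "r": config.calibration.r}
    return out


def save_config(config: ExperimentConfig, path) -> None:
    path = Path(path)
    data = config_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
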