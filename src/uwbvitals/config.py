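"""Run configuration: one YAML document drives the whole pipeline.

Every radar operating parameter is surfaced with its default (600 kHz PRF,
30 averaged acquisitions, 682-sample segments, fifth-order Butterworth pair
at normalized cutoffs 0.0212/0.1036, length-7 slow-time smoothing).
Unknown keys are rejected by name; a config round-trips losslessly through
:func:`save_config` / :func:`load_config`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cirss import CirssConfig
from .preprocess import PreprocessConfig, SmoothingConfig
from .range_est import CwtSpec
from .signal_model import (PulseSpec, SceneConfig, StaticScatterer,
                           TargetPlacement, TimingSpec, VitalSignProfile)

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config",
           "config_from_dict", "config_to_dict"]


class ConfigError(ValueError):
    """Raised with the offending key named."""


@dataclass
class ToaSection:
    threshold_factor: float = 6.0
    guard: int | None = None  # None -> pulse support in bins
    max_iter: int = 256


@dataclass
class ArraySection:
    enabled: bool = False
    spacing_m: float | None = None  # None -> half carrier wavelength
    phi_min_deg: float = -60.0
    phi_max_deg: float = 60.0
    phi_step_deg: float = 1.0


@dataclass
class MetricsSection:
    peak_halfwidth_hz: float = 0.05


@dataclass
class RunConfig:
    """Everything a pipeline run needs, nested per stage."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    timing: TimingSpec = field(default_factory=TimingSpec)
    pulse: PulseSpec = field(default_factory=PulseSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    range_est: CwtSpec = field(default_factory=CwtSpec)
    toa: ToaSection = field(default_factory=ToaSection)
    array: ArraySection = field(default_factory=ArraySection)
    cirss: CirssConfig = field(default_factory=CirssConfig)
    metrics: MetricsSection = field(default_factory=MetricsSection)
    seed: int = 0


def _build(cls, data: dict, context: str):
    """Instantiate a flat dataclass from a dict, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigError(f"section '{context}' must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(
            f"unknown key '{context}.{sorted(unknown)[0]}'")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section '{context}': {exc}")


def _scene_from_dict(data: dict) -> SceneConfig:
    if not isinstance(data, dict):
        raise ConfigError("section 'scene' must be a mapping")
    allowed = {"targets", "statics", "trend_slope", "awgn_sigma",
               "nonstat_clutter_sigma", "seed"}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key 'scene.{sorted(unknown)[0]}'")
    targets = []
    for i, t in enumerate(data.get("targets", []) or []):
        t = dict(t)
        extras = {k: t.pop(k) for k in
                  ("azimuth_deg", "elevation_deg", "reflectivity")
                  if k in t}
        prof = _build(VitalSignProfile, t, f"scene.targets[{i}]")
        targets.append(TargetPlacement(profile=prof, **extras))
    statics = [_build(StaticScatterer, dict(s), f"scene.statics[{i}]")
               for i, s in enumerate(data.get("statics", []) or [])]
    return SceneConfig(
        targets=targets, statics=statics,
        trend_slope=data.get("trend_slope", 0.0),
        awgn_sigma=data.get("awgn_sigma", 0.0),
        nonstat_clutter_sigma=data.get("nonstat_clutter_sigma", 0.0),
        seed=data.get("seed", 0))


def _preprocess_from_dict(data: dict) -> PreprocessConfig:
    data = dict(data)
    smooth = data.pop("smooth_len", None)
    cfg = _build(PreprocessConfig, data, "preprocess")
    if smooth is not None:
        cfg.smoothing = SmoothingConfig(block=int(smooth))
    return cfg


def _cirss_from_dict(data: dict) -> CirssConfig:
    data = dict(data)
    for key in ("rr_band", "hr_band"):
        if key in data:
            data[key] = tuple(float(v) for v in data[key])
    return _build(CirssConfig, data, "cirss")


_SECTIONS = {
    "scene": _scene_from_dict,
    "timing": lambda d: _build(TimingSpec, d, "timing"),
    "pulse": lambda d: _build(PulseSpec, d, "pulse"),
    "preprocess": _preprocess_from_dict,
    "range_est": lambda d: _build(CwtSpec, d, "range_est"),
    "toa": lambda d: _build(ToaSection, d, "toa"),
    "array": lambda d: _build(ArraySection, d, "array"),
    "cirss": _cirss_from_dict,
    "metrics": lambda d: _build(MetricsSection, d, "metrics"),
}


def config_from_dict(data: dict | None) -> RunConfig:
    """Build a validated RunConfig; absent sections take radar defaults."""
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(data) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown key '{sorted(unknown)[0]}'")
    kwargs = {}
    for name, builder in _SECTIONS.items():
        if name in data:
            kwargs[name] = builder(data[name])
    return RunConfig(seed=int(data.get("seed", 0)), **kwargs)


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, list):
        return [_as_plain(v) for v in obj]
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj


def config_to_dict(cfg: RunConfig) -> dict:
    """Plain-dict form (suitable for YAML) of a RunConfig."""
    out = {}
    scene = {
        "targets": [
            {**_as_plain(t.profile), "azimuth_deg": t.azimuth_deg,
             "elevation_deg": t.elevation_deg,
             "reflectivity": t.reflectivity}
            for t in cfg.scene.targets],
        "statics": [_as_plain(s) for s in cfg.scene.statics],
        "trend_slope": cfg.scene.trend_slope,
        "awgn_sigma": cfg.scene.awgn_sigma,
        "nonstat_clutter_sigma": cfg.scene.nonstat_clutter_sigma,
        "seed": cfg.scene.seed,
    }
    out["scene"] = scene
    out["timing"] = _as_plain(cfg.timing)
    out["pulse"] = _as_plain(cfg.pulse)
    pre = _as_plain(cfg.preprocess)
    pre["smooth_len"] = pre.pop("smoothing")["block"]
    out["preprocess"] = pre
    out["range_est"] = _as_plain(cfg.range_est)
    out["toa"] = _as_plain(cfg.toa)
    out["array"] = _as_plain(cfg.array)
    cir = _as_plain(cfg.cirss)
    cir.pop("lambda_grid", None)  # derived default, not user-facing
    out["cirss"] = cir
    out["metrics"] = _as_plain(cfg.metrics)
    out["seed"] = cfg.seed
    return out


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}")
    return config_from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
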