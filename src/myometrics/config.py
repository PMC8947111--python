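"""Structured configuration: every pipeline parameter has an explicit named
default (the published values), so reproducing the reference analysis is the
zero-config behavior.  Overrides from a YAML/JSON file are logged."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import yaml

from .ecm import EcmConfig
from .fibers import FiberPipelineConfig
from .imaging import ThresholdSpec
from .macrophages import MacrophagePipelineConfig
from .nuclei import NucleiPipelineConfig

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for malformed configuration files or unknown keys."""


def _flatten(cfg) -> dict:
    out = {}
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if isinstance(v, ThresholdSpec):
            out[f.name] = {
                "method": v.method,
                "middle_class_to": v.middle_class_to,
                "scope": v.scope,
                "window_px": v.window_px,
                "log_transform": v.log_transform,
            }
        elif dataclasses.is_dataclass(v) or isinstance(v, tuple) and v and dataclasses.is_dataclass(v[0]):
            continue  # stain vectors: overridable via explicit API, not flat keys
        else:
            out[f.name] = list(v) if isinstance(v, tuple) else v
    return out


def default_config() -> dict:
    return {
        "fibers": _flatten(FiberPipelineConfig()),
        "nuclei": _flatten(NucleiPipelineConfig()),
        "cells": _flatten(MacrophagePipelineConfig()),
        "ecm": _flatten(EcmConfig()),
    }


def load_config(path=None) -> dict:
    """Defaults merged with the overrides in ``path`` (YAML or JSON)."""
    cfg = default_config()
    if path is None:
        return cfg
    path = Path(path)
    try:
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (OSError, ValueError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if data is None:
        return cfg
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a mapping of pipeline sections")
    for section, overrides in data.items():
        if section not in cfg:
            raise ConfigError(f"unknown config section {section!r}")
        if not isinstance(overrides, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        for key, value in overrides.items():
            if key not in cfg[section]:
                raise ConfigError(f"unknown key {section}.{key}")
            log.info("config override: %s.%s = %r (default %r)", section, key, value, cfg[section][key])
            cfg[section][key] = value
    return cfg


def _threshold_from_dict(d: dict) -> ThresholdSpec:
    return ThresholdSpec(
        method=d["method"],
        middle_class_to=d["middle_class_to"],
        scope=d["scope"],
        window_px=d["window_px"],
        log_transform=bool(d.get("log_transform", False)),
    )


def _build(cls, section: dict):
    kwargs = dict(section)
    if "threshold" in kwargs and isinstance(kwargs["threshold"], dict):
        kwargs["threshold"] = _threshold_from_dict(kwargs["threshold"])
    if "diameter_range" in kwargs:
        kwargs["diameter_range"] = tuple(kwargs["diameter_range"])
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration for {cls.__name__}: {exc}") from exc


def fiber_config(cfg: dict, um_per_px: float | None = None) -> FiberPipelineConfig:
    section = dict(cfg["fibers"])
    if um_per_px is not None:
        section["um_per_px"] = um_per_px
    return _build(FiberPipelineConfig, section)


def nuclei_config(cfg: dict) -> NucleiPipelineConfig:
    return _build(NucleiPipelineConfig, cfg["nuclei"])


def macrophage_config(cfg: dict) -> MacrophagePipelineConfig:
    return _build(MacrophagePipelineConfig, cfg["cells"])


def ecm_config(cfg: dict) -> EcmConfig:
    return _build(EcmConfig, cfg["ecm"])
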