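"""YAML run configuration: subtype order, fitness weights, GA and simulation
parameters, seed.  Keys mirror the GAConfig / SimConfig field names."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .ga import GAConfig
from .simulate import SimConfig


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a mapping")
    return data


def _build(cls, data: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown {section} config key(s): {sorted(unknown)}")
    for key in ("subtype_order", "proportions", "baseline_hazards"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {section} config: {exc}") from exc


def ga_config(data: dict, **overrides) -> GAConfig:
    section = dict(data.get("ga", {}))
    section.update(overrides)
    return _build(GAConfig, section, "ga")


def sim_config(data: dict, **overrides) -> SimConfig:
    section = dict(data.get("simulate", {}))
    section.update(overrides)
    return _build(SimConfig, section, "simulate")


def subtype_order(data: dict) -> list[str]:
    order = data.get("subtype_order")
    if not order:
        raise ConfigError("config key 'subtype_order' is required")
    return [str(s) for s in order]


def write_example_config(path) -> None:
    """An example configuration for the breast-cancer setting."""
    sim = SimConfig()
    example = {
        "subtype_order": list(sim.subtype_order),
        "ga": {k: v for k, v in dataclasses.asdict(GAConfig()).items()},
        "simulate": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(sim).items()
        },
    }
    Path(path).write_text(yaml.safe_dump(example, sort_keys=False))
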