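"""TOML run-configuration loading and typed-object builders.

A run config is a TOML file with optional sections ``[scenario]``,
``[protein]``, ``[starch]``, ``[partition]``, ``[calibration]``,
``[observations]`` and ``[io]`` plus a top-level ``seed``.  Absent sections
fall back to the calibrated defaults, so an empty file is a valid config.
"""

from __future__ import annotations

import tomllib
from dataclasses import fields
from pathlib import Path

from .calibration import Bounds, GAConfig
from .protein import ProteinParams
from .starch import PartitionParams, StarchParams
from .synthetic import ScenarioConfig, StressWindow

__all__ = [
    "load_config", "scenario_from_config", "protein_params_from_config",
    "starch_params_from_config", "partition_params_from_config",
    "ga_config_from_config", "bounds_from_config",
]


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _pick(section: dict, cls) -> dict:
    known = {f.name for f in fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(
            f"unknown {cls.__name__} option(s): {sorted(unknown)}")
    return dict(section)


def scenario_from_config(config: dict, seed: int | None = None
                         ) -> ScenarioConfig:
    section = dict(config.get("scenario", {}))
    windows = []
    for w in section.pop("stress_windows", []):
        if isinstance(w, dict):
            windows.append(StressWindow(**w))
        else:
            windows.append(StressWindow(*w))
    kwargs = _pick(section, ScenarioConfig)
    kwargs["stress_windows"] = windows
    if seed is not None:
        kwargs["seed"] = seed
    elif "seed" not in kwargs and "seed" in config:
        kwargs["seed"] = int(config["seed"])
    return ScenarioConfig(**kwargs)


def protein_params_from_config(config: dict) -> ProteinParams:
    return ProteinParams(**_pick(config.get("protein", {}), ProteinParams))


def starch_params_from_config(config: dict) -> StarchParams:
    return StarchParams(**_pick(config.get("starch", {}), StarchParams))


def partition_params_from_config(config: dict) -> PartitionParams:
    return PartitionParams(**_pick(config.get("partition", {}),
                                   PartitionParams))


def ga_config_from_config(config: dict, seed: int | None = None) -> GAConfig:
    section = dict(config.get("calibration", {}).get("ga", {}))
    if seed is not None:
        section["seed"] = seed
    elif "seed" not in section and "seed" in config:
        section["seed"] = int(config["seed"])
    return GAConfig(**_pick(section, GAConfig))


def bounds_from_config(config: dict, stage: str, default: Bounds) -> Bounds:
    section = config.get("calibration", {}).get("bounds", {}).get(stage)
    if not section:
        return default
    return Bounds.from_dict({k: (float(v[0]), float(v[1]))
                             for k, v in section.items()})
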