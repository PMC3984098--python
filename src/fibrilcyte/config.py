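"""YAML run configuration with validated experiment-grade defaults.

An empty file (or missing section) yields the full default experiment:
40 um fibril spacing imaged at 0.51 um/px, 100 cells/mm^2, inhibitor doses
{0, 0.5, 2.5, 5, 25, 50} uM, and AFM calibration (half-angle 15 deg,
nu 0.5, k_tip 2.0 N/m, sensitivity 28 nm/V). Unknown keys are rejected so
typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .afm_sim import TipCalibration
from .cells import CellPopulationModel, ImagingModel
from .fibril import FibrilArraySpec

__all__ = ["RunConfig", "ConfigError", "load_config", "config_to_dict"]

DEFAULT_DOSES_UM = (0.0, 0.5, 2.5, 5.0, 25.0, 50.0)


class ConfigError(ValueError):
    """A configuration file violates the schema."""


@dataclass
class StatsOptions:
    alignment_threshold_deg: float = 20.0
    perimeter_bin_um: float = 20.0
    envelope_quantiles: tuple[float, float] = (0.025, 0.975)
    od_about_zero: bool = False


@dataclass
class AfmOptions:
    indent_cap_nm: float = 100.0
    segment: str = "retract"
    grid: tuple[int, int] = (32, 32)
    extent_um: tuple[float, float] = (10.0, 10.0)
    E_fibril_pa: float = 226e3
    E_base_pa: float = 1e6
    noise_sd_nn: float = 0.0
    fibril_width_um: float = 4.0


@dataclass
class RunConfig:
    """Fully resolved run configuration."""

    fibril: FibrilArraySpec = field(default_factory=FibrilArraySpec)
    cells: CellPopulationModel = field(default_factory=CellPopulationModel)
    imaging: ImagingModel = field(default_factory=ImagingModel)
    calibration: TipCalibration = field(default_factory=TipCalibration)
    stats: StatsOptions = field(default_factory=StatsOptions)
    afm: AfmOptions = field(default_factory=AfmOptions)
    doses_um: tuple[float, ...] = DEFAULT_DOSES_UM
    conditions: tuple[str, ...] = ("fibril", "flat")
    seed: int = 0
    include_afm: bool = True

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.doses_um):
            raise ConfigError("doses must be nonnegative")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        for c in self.conditions:
            if c not in ("fibril", "flat"):
                raise ConfigError(f"unknown condition {c!r}")


_SECTIONS = {
    "fibril": FibrilArraySpec,
    "cells": CellPopulationModel,
    "imaging": ImagingModel,
    "calibration": TipCalibration,
    "stats": StatsOptions,
    "afm": AfmOptions,
}
_SCALARS = {"doses_um", "conditions", "seed", "include_afm"}


def _build_section(cls, data: dict, name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section '{name}'")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        coerced[f.name] = tuple(v) if isinstance(v, list) else v
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section '{name}': {exc}") from exc


def load_config(path: Optional[str | Path] = None) -> RunConfig:
    """Load and validate a YAML config; None or an empty file gives defaults."""
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("top level of the config must be a mapping")
    unknown = set(data) - set(_SECTIONS) - _SCALARS
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"section '{name}' must be a mapping")
        kwargs[name] = _build_section(cls, section, name)
    for name in _SCALARS:
        if name in data:
            v = data[name]
            kwargs[name] = tuple(v) if isinstance(v, list) else v
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def config_to_dict(cfg: RunConfig) -> dict:
    """Serializable dict of a config (for provenance records)."""
    return dataclasses.asdict(cfg)
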