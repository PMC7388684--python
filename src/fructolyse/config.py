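"""Run configuration: file + CLI merging, validation, CSV round-trip.

A run is fully specified by a :class:`RunConfig`; precedence is
CLI arguments > config file > documented defaults, and unknown keys fail
fast with the offending name.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .diet import DietSpec, scenario_diets
from .kinetics import STOICHIOMETRY_MODES

__all__ = ["RunConfig", "ConfigError", "parse_config", "dump_config",
           "read_timeseries"]

SCENARIOS = ("diet", "oat", "khk", "single")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Fully resolved description of one invocation."""

    scenario: str = "single"
    params_path: str | None = None  # None = packaged defaults
    overrides: dict[str, float] = field(default_factory=dict)
    diet_preset: str | None = "mixed-100g"
    grams_per_meal: float | None = None
    fructose_fraction: float | None = None
    perturbation: float = 0.10
    inhibition_fractions: tuple[float, ...] = (0.0, 0.5, 0.7, 1.0)
    horizon_h: float = 12.0
    report_dt_min: float = 1.0
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "LSODA"
    stoichiometry_mode: str = "paper-faithful"
    out_dir: str = "fructolyse-out"

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        if self.stoichiometry_mode not in STOICHIOMETRY_MODES:
            raise ConfigError(
                f"unknown stoichiometry_mode {self.stoichiometry_mode!r}"
            )
        if self.diet_preset is not None and (
            self.grams_per_meal is not None or self.fructose_fraction is not None
        ):
            raise ConfigError(
                "give either diet_preset or grams_per_meal/fructose_fraction, "
                "not both"
            )
        if self.diet_preset is not None and self.diet_preset not in scenario_diets():
            raise ConfigError(f"unknown diet preset {self.diet_preset!r}")
        if self.horizon_h <= 0:
            raise ConfigError("horizon_h must be > 0")

    def resolve_diet(self) -> DietSpec:
        if self.diet_preset is not None:
            return scenario_diets()[self.diet_preset]
        grams = 100.0 if self.grams_per_meal is None else self.grams_per_meal
        frac = 0.5 if self.fructose_fraction is None else self.fructose_fraction
        return DietSpec(grams, frac, name="custom")


_FIELDS = set(RunConfig.__dataclass_fields__)


def parse_config(
    path: str | Path | None = None,
    cli_args: Mapping[str, object] | None = None,
) -> RunConfig:
    """Merge defaults <- config file <- CLI arguments into a RunConfig."""
    merged: dict[str, object] = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        for key, value in doc.items():
            if key not in _FIELDS:
                raise ConfigError(f"{path}: unknown config key {key!r}")
            merged[key] = value
    if cli_args:
        explicit_preset = cli_args.get("diet_preset") is not None
        for key, value in cli_args.items():
            if key not in _FIELDS:
                raise ConfigError(f"unknown config key {key!r}")
            if value is not None:
                merged[key] = value
        # custom meal fields on the command line replace any preset unless
        # a preset was itself given explicitly
        if not explicit_preset and (
            cli_args.get("grams_per_meal") is not None
            or cli_args.get("fructose_fraction") is not None
        ):
            merged["diet_preset"] = None
    if "inhibition_fractions" in merged:
        merged["inhibition_fractions"] = tuple(
            float(x) for x in merged["inhibition_fractions"]  # type: ignore
        )
    if "overrides" in merged:
        merged["overrides"] = {
            str(k): float(v) for k, v in dict(merged["overrides"]).items()  # type: ignore
        }
    cfg = RunConfig(**merged)  # type: ignore[arg-type]
    cfg.validate()
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the resolved config; re-parsing yields an identical run."""
    doc = asdict(cfg)
    doc["inhibition_fractions"] = list(cfg.inhibition_fractions)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_timeseries(path: str | Path) -> pd.DataFrame:
    """Read back a trajectory CSV written by a SimulationResult."""
    return pd.read_csv(path, float_precision="round_trip")
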