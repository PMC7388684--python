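"""Named-constant registry for the fructose-metabolism model.

Every rate law in :mod:`fructolyse.kinetics`, :mod:`fructolyse.exchange`
and :mod:`fructolyse.diet` draws its constants from a :class:`ParameterSet`
loaded from a plain-text YAML document.  The registry is closed-world: a
file that does not define every required identifier fails to load, so a
typo in the parameter file surfaces at start-up rather than mid-integration.

Units convention: concentrations in uM (micromol/L), rates in uM/s, time
constants in 1/s, volumes in L.  Hormones are dimensionless multiples of
their basal reference level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "Parameter",
    "ParameterSet",
    "ParameterError",
    "REQUIRED_PARAMETERS",
    "default_parameter_path",
    "load_parameters",
    "save_parameters",
    "perturb_parameter",
]

VALID_UNITS = {"uM", "uM/s", "dimensionless", "1/s", "L", "g", "h"}
VALID_PROVENANCE = {"SM1", "SM2-code", "reconstructed", "config-override"}


class ParameterError(ValueError):
    """Raised on a missing identifier or an invariant violation."""


@dataclass(frozen=True)
class Parameter:
    name: str
    value: float
    units: str = "dimensionless"
    provenance: str = "reconstructed"

    def validate(self) -> None:
        if not math.isfinite(self.value):
            raise ParameterError(f"{self.name}: value is not finite")
        if self.units not in VALID_UNITS:
            raise ParameterError(f"{self.name}: unknown units {self.units!r}")
        if self.provenance not in VALID_PROVENANCE:
            raise ParameterError(
                f"{self.name}: unknown provenance {self.provenance!r}"
            )
        cls = _param_class(self.name)
        if cls == "positive" and not self.value > 0:
            raise ParameterError(
                f"{self.name}: V_max/K_m-class parameter must be > 0, "
                f"got {self.value}"
            )
        if cls == "beta" and not (0.0 <= self.value <= 1.0):
            raise ParameterError(
                f"{self.name}: inhibition strength must lie in [0, 1], "
                f"got {self.value}"
            )
        if cls == "hill" and not self.value >= 1.0:
            raise ParameterError(
                f"{self.name}: Hill exponent must be >= 1, got {self.value}"
            )


def _param_class(name: str) -> str:
    """Validation class from the identifier's conventional prefix."""
    if name.startswith("beta_"):
        return "beta"
    if name.startswith("n_"):
        return "hill"
    if name.startswith(("V_", "Km_", "Ki_", "ki_", "K_")):
        return "positive"
    return "other"


# --- required identifiers, grouped as in the parameter file -----------------

_HEPATIC = [
    # fructolysis
    "V_KHK", "Km_KHK", "n_Fru", "Km_ATP", "n_ATP",
    "V_aldB", "Km_F1P", "n_F1P",
    "V_TPI_DHAP", "Km_DHAP", "n_DHAP", "V_TPI_GA3P", "Km_TPIGA3P", "n_GA3P",
    "V_Tri", "Km_GA", "n_GA", "Km_ATPMg", "n_ATPMg",
    "beta_ATP", "Ki_ATP", "beta_ADP", "Ki_ADP",
    # lower glycolysis / gluconeogenesis
    "V_PK", "Km_GA3P", "Km_ADPpk", "n_ADPpk", "beta_ACoA_PK", "Ki_ACoA_PK",
    "V_PEPCK", "Km_PEPCK", "Km_ATPpepck", "Km_GTP",
    "V_PDC", "Km_Pyr", "beta_ACoA_PDC", "ki_CoA_pyr",
    # lipid metabolism
    "V_FAS", "Km_ACoA", "Km_ATPfas", "beta_FA", "ki_FA_inhib",
    "V_boxi", "Km_boxi", "Km_ATPboxi", "beta_boxi", "ki_CoA_boxi",
    "beta_PPARa", "ki_F1P_inhib",
    "V_TGS", "Km_FA", "Km_TGSGA3P",
    "V_Lply", "Km_TG",
    # glucose branch
    "V_GK", "Km_Glu", "n_Glu", "Km_ATPgk", "ki_G6P",
    "V_G6Pase", "Km_G6Pase",
    "V_FBP", "Km_FBP",
    "V_PFK", "Km_PFK", "Km_ATPpfk", "ki_ATPfpk", "ki_ADPfpk",
    "beta_PFK", "ki_GA3Ppfk",
]

_TRANSPORT = [
    "V_GLUT2pump", "Km_GLUT2pump", "V_GLUT2ex", "Km_GLUT2ex",
    "V_GLUT5pump", "Km_GLUT5pump", "V_GLUT5ex", "Km_GLUT5ex",
    "V_GLUTGpump", "Km_GLUTGpump", "V_GLUTGex", "Km_GLUTGex",
    "V_Pyrex", "Km_Pyrex",
    "V_FAex", "Km_FAex", "V_active", "Km_active", "Insref_active",
    "V_TGex", "Km_TGex", "TG_ref", "V_out", "Km_out",
]

_CIRCULATION = ["R_HE", "R_BS", "R_RL", "V_body", "V_liver"]

_COFACTORS = ["ATP", "ADP", "AMP", "ATPMg", "GTP", "GDP", "NAD", "NADH", "Pi"]

_HORMONES = ["Glu_setpoint", "n_Ins", "n_Gcg", "k_Ins_clear", "k_Gcg_clear"]

_PERIPHERY = [
    "V_USE_Glu", "Km_USE_Glu", "A_Ins_Glu", "K_Ins_Glu",
    "V_USE_FA", "Km_USE_FA",
    "V_USE_TG", "Km_USE_TG",
    "V_UP_FA", "V_UP_TG", "Km_UP_Glu",
    "beta_UP_FA", "Ki_UP_FA", "beta_UP_TG", "Ki_UP_TG",
]

REQUIRED_PARAMETERS: frozenset[str] = frozenset(
    _HEPATIC + _TRANSPORT + _CIRCULATION + _COFACTORS + _HORMONES + _PERIPHERY
)


@dataclass
class ParameterSet:
    """Immutable-by-convention mapping of identifier -> :class:`Parameter`."""

    entries: dict[str, Parameter] = field(default_factory=dict)
    version: str = "unversioned"

    def __getitem__(self, name: str) -> float:
        try:
            return self.entries[name].value
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def get(self, name: str, default: float | None = None) -> float | None:
        return self.entries[name].value if name in self.entries else default

    def names(self) -> list[str]:
        return sorted(self.entries)

    def copy(self) -> "ParameterSet":
        return ParameterSet(entries=dict(self.entries), version=self.version)

    def validate(self) -> None:
        """Check entry invariants, closed-world coverage and derived ratios."""
        for p in self.entries.values():
            p.validate()
        missing = REQUIRED_PARAMETERS - set(self.entries)
        if missing:
            raise ParameterError(
                "missing required parameter(s): " + ", ".join(sorted(missing))
            )
        r_rl = (self["V_body"] - self["V_liver"]) / self["V_liver"]
        if abs(self["R_RL"] - r_rl) > 1e-9:
            raise ParameterError(
                f"R_RL={self['R_RL']} inconsistent with "
                f"(V_body - V_liver)/V_liver = {r_rl}"
            )


def default_parameter_path() -> Path:
    """Path of the parameter file shipped with the package."""
    return Path(
        resources.files("fructolyse").joinpath("data/default_parameters.yaml")
    )


def load_parameters(
    path: str | Path | None = None,
    overrides: Mapping[str, float] | None = None,
) -> ParameterSet:
    """Load and validate a parameter file, applying optional overrides.

    Parameters
    ----------
    path
        YAML parameter file; ``None`` uses the packaged default set.
    overrides
        Mapping of identifier -> new value.  Keys must already exist in the
        file; each override is retagged ``provenance=config-override``.
    """
    path = default_parameter_path() if path is None else Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ParameterError(f"{path}: not a mapping document")
    version = str(doc.pop("version", path.name))
    entries: dict[str, Parameter] = {}
    for section, block in doc.items():
        if not isinstance(block, dict):
            raise ParameterError(f"{path}: section {section!r} is not a mapping")
        for name, spec in block.items():
            if name in entries:
                raise ParameterError(f"{path}: duplicate parameter {name!r}")
            if isinstance(spec, dict):
                entries[name] = Parameter(
                    name=name,
                    value=float(spec["value"]),
                    units=str(spec.get("units", "dimensionless")),
                    provenance=str(spec.get("provenance", "reconstructed")),
                )
            else:
                entries[name] = Parameter(name=name, value=float(spec))
    params = ParameterSet(entries=entries, version=version)
    if overrides:
        unknown = set(overrides) - set(entries)
        if unknown:
            raise ParameterError(
                "override for unknown parameter(s): " + ", ".join(sorted(unknown))
            )
        for name, value in overrides.items():
            old = entries[name]
            entries[name] = replace(
                old, value=float(value), provenance="config-override"
            )
    params.validate()
    return params


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a ParameterSet back to YAML (exact float round-trip)."""
    doc: dict[str, dict] = {"version": params.version, "parameters": {}}
    for name in sorted(params.entries):
        p = params.entries[name]
        doc["parameters"][name] = {
            "value": p.value,
            "units": p.units,
            "provenance": p.provenance,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def perturb_parameter(
    params: ParameterSet, name: str, factor: float
) -> ParameterSet:
    """Return a copy with exactly one value multiplied by ``factor``.

    The original set is untouched; this is the primitive behind the
    one-at-a-time sensitivity sweep and the KHK-inhibition scenario.
    """
    if factor < 0:
        raise ValueError(f"perturbation factor must be >= 0, got {factor}")
    if name not in params.entries:
        raise KeyError(f"unknown parameter {name!r}")
    out = params.copy()
    old = out.entries[name]
    out.entries[name] = replace(old, value=old.value * factor)
    return out


def perturb_many(
    params: ParameterSet, scales: Mapping[str, float]
) -> ParameterSet:
    out = params.copy()
    for name, factor in scales.items():
        out = perturb_parameter(out, name, factor)
    return out
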