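"""The three study scenarios as deterministic, report-producing runners.

* Diet comparison: 100 g/meal of pure fructose, 50:50 mix, or pure
  glucose, run 12 h from a shared mixed-diet baseline; lipid trajectories
  and endpoints.
* One-at-a-time (OAT) sensitivity: each of the 11 key hepatic rate
  constants perturbed by +/-10% in turn; change in the 12-h hepatic and
  plasma fatty-acid / triglyceride endpoints versus the unperturbed run.
* KHK inhibition: very-high-fructose (150 g/meal) runs with fructokinase
  V_max scaled by (1 - fraction) for fractions 0, 0.5, 0.7, 1.0, plus the
  steatosis setup metric (percent hepatic-TG excess of the 150 g over the
  100 g fructose diet).

"Plasma" in reports always means the systemic blood compartment (SBC),
the thing clinical measurements see.  Endpoints are state values at
t = 12 h; every runner is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diet import DietSpec, scenario_diets
from .parameters import ParameterSet, perturb_parameter
from .simulator import SimulationResult, run_simulation, run_to_baseline

__all__ = [
    "OAT_TARGETS",
    "ENDPOINT_COLUMNS",
    "DietComparisonResult",
    "SensitivityReport",
    "InhibitionResult",
    "run_diet_comparison",
    "run_oat_sensitivity",
    "run_khk_inhibition",
    "write_report",
]

# Table-6-style target list: display label -> V_max parameter(s) scaled.
# TPI is one enzyme with two directional V_max entries; both scale together.
OAT_TARGETS: dict[str, tuple[str, ...]] = {
    "KHK": ("V_KHK",),
    "aldB": ("V_aldB",),
    "TPI": ("V_TPI_DHAP", "V_TPI_GA3P"),
    "Tri": ("V_Tri",),
    "PK": ("V_PK",),
    "PEPCK": ("V_PEPCK",),
    "PDC": ("V_PDC",),
    "FAS": ("V_FAS",),
    "boxi": ("V_boxi",),
    "TGS": ("V_TGS",),
    "Lply": ("V_Lply",),
}

# the four reported outputs and the state columns they read
ENDPOINT_COLUMNS = {
    "hepatic_FA": "FA_SH",
    "hepatic_TG": "TG_SH",
    "plasma_FA": "FA_SBC",
    "plasma_TG": "TG_SBC",
}

_SOLVER_KEYS = ("rtol", "atol", "method", "mode")


def _solver_kwargs(kw: dict) -> dict:
    out = {}
    for k in _SOLVER_KEYS:
        if k in kw:
            out[k] = kw[k]
    return out


def _endpoints(result: SimulationResult) -> dict[str, float]:
    return {
        label: result.endpoint(col) for label, col in ENDPOINT_COLUMNS.items()
    }


@dataclass
class DietComparisonResult:
    results: dict[str, SimulationResult]
    summary: pd.DataFrame  # one row per diet, endpoint columns
    baseline_state: np.ndarray


@dataclass
class SensitivityReport:
    """OAT sensitivity grid: 11 reactions x (4 outputs x 2 directions)."""

    deltas: pd.DataFrame  # index = reaction label; columns <output>_{plus,minus}
    baseline_endpoints: dict[str, float]
    perturbation: float
    config: dict = field(default_factory=dict)


@dataclass
class InhibitionResult:
    results: dict[float, SimulationResult]  # keyed by inhibition fraction
    endpoints: pd.DataFrame  # one row per fraction
    steatosis_increase_pct: float
    reference_runs: dict[str, SimulationResult]


def run_diet_comparison(
    diets: list[DietSpec] | dict[str, DietSpec] | None = None,
    params: ParameterSet | None = None,
    *,
    baseline_state: np.ndarray | None = None,
    horizon_h: float = 12.0,
    **solver,
) -> DietComparisonResult:
    """Run the diet-comparison scenario.

    All diets start from the identical mixed-diet run-in state, so curves
    differ only through the meals themselves.
    """
    if params is None:
        raise ValueError("params is required")
    presets = scenario_diets()
    if diets is None:
        diets = [presets["fructose-100g"], presets["mixed-100g"],
                 presets["glucose-100g"]]
    if isinstance(diets, dict):
        diets = list(diets.values())
    if not diets:
        raise ValueError("need at least one diet")
    if baseline_state is None:
        baseline_state = run_to_baseline(
            params, presets["mixed-100g"], **_baseline_kwargs(solver)
        )
    results: dict[str, SimulationResult] = {}
    rows = []
    for spec in diets:
        res = run_simulation(
            baseline_state, params, spec, horizon_h=horizon_h,
            **_solver_kwargs(solver),
        )
        results[spec.name] = res
        row = {"diet": spec.name, **_endpoints(res),
               "blood_glucose_12h": res.endpoint("Glu_SBC"),
               "plasma_TG_max": float(np.max(res["TG_SBC"]))}
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("diet")
    return DietComparisonResult(results, summary, baseline_state)


def _baseline_kwargs(solver: dict) -> dict:
    out = _solver_kwargs(solver)
    return out


def run_oat_sensitivity(
    params: ParameterSet,
    diet: DietSpec | None = None,
    perturbation: float = 0.10,
    targets: dict[str, tuple[str, ...]] | None = None,
    *,
    baseline_state: np.ndarray | None = None,
    horizon_h: float = 12.0,
    directions: tuple[int, ...] = (1, -1),
    **solver,
) -> SensitivityReport:
    """One-at-a-time +/- sensitivity of the 12-h lipid endpoints.

    For every target and direction one full simulation is launched with
    only that rate constant scaled by ``1 +/- perturbation``; all runs
    share the unperturbed baseline initial state and solver settings.
    """
    if perturbation <= -1:
        raise ValueError("perturbation must exceed -1")
    if diet is None:
        diet = scenario_diets()["mixed-100g"]
    if targets is None:
        targets = OAT_TARGETS
    unknown = [
        n for names in targets.values() for n in names if n not in params
    ]
    if unknown:
        raise KeyError(f"unknown sensitivity target parameter(s): {unknown}")
    if baseline_state is None:
        baseline_state = run_to_baseline(params, diet, **_baseline_kwargs(solver))
    sk = _solver_kwargs(solver)
    base_res = run_simulation(
        baseline_state, params, diet, horizon_h=horizon_h, **sk
    )
    base_ep = _endpoints(base_res)
    records: dict[str, dict[str, float]] = {}
    for label, names in targets.items():
        records[label] = {}
        for direction in directions:
            factor = 1.0 + direction * perturbation
            pset = params
            for n in names:
                pset = perturb_parameter(pset, n, factor)
            res = run_simulation(
                baseline_state, pset, diet, horizon_h=horizon_h, **sk
            )
            ep = _endpoints(res)
            tag = "plus" if direction > 0 else "minus"
            for out_label in ENDPOINT_COLUMNS:
                records[label][f"{out_label}_{tag}"] = (
                    ep[out_label] - base_ep[out_label]
                )
    deltas = pd.DataFrame.from_dict(records, orient="index")
    deltas = deltas.loc[list(targets)]
    return SensitivityReport(
        deltas=deltas,
        baseline_endpoints=base_ep,
        perturbation=perturbation,
        config=dict(base_res.config),
    )


def run_khk_inhibition(
    params: ParameterSet,
    fractions: tuple[float, ...] = (0.0, 0.5, 0.7, 1.0),
    *,
    baseline_state: np.ndarray | None = None,
    horizon_h: float = 12.0,
    **solver,
) -> InhibitionResult:
    """KHK-suppression scenario on the very-high-fructose diet.

    Also runs the 100 g and 150 g uninhibited fructose diets to compute
    the steatosis setup metric: percent increase of the 12-h hepatic TG
    endpoint of the 150 g diet over the 100 g diet.
    """
    if any(f < 0 or f > 1 for f in fractions):
        raise ValueError("inhibition fractions must lie in [0, 1]")
    presets = scenario_diets()
    high, normal = presets["fructose-150g"], presets["fructose-100g"]
    if baseline_state is None:
        baseline_state = run_to_baseline(
            params, presets["mixed-100g"], **_baseline_kwargs(solver)
        )
    sk = _solver_kwargs(solver)
    ref_100 = run_simulation(
        baseline_state, params, normal, horizon_h=horizon_h, **sk
    )
    ref_150 = run_simulation(
        baseline_state, params, high, horizon_h=horizon_h, **sk
    )
    tg100, tg150 = ref_100.endpoint("TG_SH"), ref_150.endpoint("TG_SH")
    steatosis_pct = 100.0 * (tg150 - tg100) / tg100
    results: dict[float, SimulationResult] = {}
    rows = []
    for frac in fractions:
        if frac == 0.0:
            res = ref_150
        else:
            pset = perturb_parameter(params, "V_KHK", 1.0 - frac)
            res = run_simulation(
                baseline_state, pset, high, horizon_h=horizon_h, **sk
            )
        results[frac] = res
        rows.append({"inhibition_fraction": frac, **_endpoints(res)})
    endpoints = pd.DataFrame(rows).set_index("inhibition_fraction")
    return InhibitionResult(
        results=results,
        endpoints=endpoints,
        steatosis_increase_pct=steatosis_pct,
        reference_runs={"fructose-100g": ref_100, "fructose-150g": ref_150},
    )


def write_report(result, path) -> list[Path]:
    """Write CSV tables plus a JSON run manifest for any scenario result.

    Returns the list of files written.
    """
    outdir = Path(path)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create report directory {outdir}: {exc}") from exc
    written: list[Path] = []

    def _manifest(extra: dict, configs: dict) -> None:
        man = outdir / "manifest.json"
        with open(man, "w") as fh:
            json.dump({"runs": configs, **extra}, fh, indent=2, default=str)
        written.append(man)

    if isinstance(result, DietComparisonResult):
        for name, res in result.results.items():
            f = outdir / f"trajectory_{name}.csv"
            res.to_csv(f)
            written.append(f)
        f = outdir / "diet_summary.csv"
        result.summary.to_csv(f)
        written.append(f)
        _manifest({}, {n: r.config for n, r in result.results.items()})
    elif isinstance(result, SensitivityReport):
        f = outdir / "sensitivity.csv"
        result.deltas.to_csv(f)
        written.append(f)
        _manifest(
            {
                "perturbation": result.perturbation,
                "baseline_endpoints": result.baseline_endpoints,
            },
            {"baseline": result.config},
        )
    elif isinstance(result, InhibitionResult):
        for frac, res in result.results.items():
            f = outdir / f"trajectory_khk_{int(round(frac * 100)):03d}.csv"
            res.to_csv(f)
            written.append(f)
        f = outdir / "inhibition_endpoints.csv"
        result.endpoints.to_csv(f)
        written.append(f)
        _manifest(
            {"steatosis_increase_pct": result.steatosis_increase_pct},
            {str(fr): r.config for fr, r in result.results.items()},
        )
    elif isinstance(result, SimulationResult):
        f = outdir / "trajectory.csv"
        result.to_csv(f, include_fluxes=result.rates is not None)
        written.append(f)
        _manifest({}, {"run": result.config})
    else:
        raise TypeError(f"cannot write a report for {type(result).__name__}")
    return written
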