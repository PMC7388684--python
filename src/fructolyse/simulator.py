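"""Assembly and integration of the full 25-state model.

State layout (fixed, documented order)::

    indices  0-10  hepatocyte:      Fru, F1P, DHAP, GA, GA3P, Pyr, ACoA,
                                    FA, TG, Glu, G6P            (uM)
    indices 11-17  hepatic blood:   Fru, Glu, Pyr, FA, TG, Ins, Gcg
    indices 18-24  systemic blood:  Fru, Glu, Pyr, FA, TG, Ins, Gcg

That is 11 hepatocyte metabolites, 5 blood metabolites in each of two
blood compartments, and insulin/glucagon in each blood compartment: 25
first-order ODEs.  The simulation clock starts at t=0 = 08:00; meals
repeat every 24 h.  Integration is adaptive and stiff-capable (LSODA by
default) at tight tolerances; concentrations are never clipped, so a
stoichiometry bug shows up as a negative trajectory instead of being
masked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .diet import DietSpec, meal_input_rate, zero_diet
from .exchange import (
    BloodState,
    TransportVector,
    circulation_pair,
    evaluate_transports,
    hormone_derivatives,
    periphery_fluxes,
)
from .kinetics import (
    STOICHIOMETRY_MODES,
    HepaticState,
    RateVector,
    evaluate_hepatic_rates,
    hepatic_derivatives,
)
from .parameters import ParameterSet

__all__ = [
    "STATE_NAMES",
    "N_STATES",
    "FullState",
    "SimulationResult",
    "SimulationError",
    "assemble_derivatives",
    "run_simulation",
    "run_to_baseline",
    "find_equilibrium",
    "default_initial_state",
    "carbon_audit",
    "CARBON_WEIGHTS",
]

_HEPATIC_NAMES = [f"{n}_SH" for n in HepaticState._fields]
_SHB_NAMES = [f"{n}_SHB" for n in BloodState._fields]
_SBC_NAMES = [f"{n}_SBC" for n in BloodState._fields]
STATE_NAMES: list[str] = _HEPATIC_NAMES + _SHB_NAMES + _SBC_NAMES
N_STATES = len(STATE_NAMES)
assert N_STATES == 25

_IDX = {name: i for i, name in enumerate(STATE_NAMES)}


class SimulationError(RuntimeError):
    """Integration failure; carries the last valid time and state."""

    def __init__(self, message: str, t_h: float | None = None, state=None):
        super().__init__(message)
        self.t_h = t_h
        self.state = state


class FullState(NamedTuple):
    hepatic: HepaticState
    shb: BloodState
    sbc: BloodState

    def to_array(self) -> np.ndarray:
        return np.array(list(self.hepatic) + list(self.shb) + list(self.sbc))

    @classmethod
    def from_array(cls, y) -> "FullState":
        y = np.asarray(y, dtype=float)
        if y.shape != (N_STATES,):
            raise ValueError(f"state must have shape (25,), got {y.shape}")
        return cls(
            HepaticState(*y[:11]), BloodState(*y[11:18]), BloodState(*y[18:25])
        )


def default_initial_state() -> np.ndarray:
    """A physiologically plausible cold-start state (uM; hormones at basal).

    Only used to seed the run-in; scenario runs start from the converged
    baseline returned by :func:`run_to_baseline`.
    """
    hepatic = HepaticState(
        Fru=10.0, F1P=100.0, DHAP=50.0, GA=20.0, GA3P=100.0, Pyr=300.0,
        ACoA=80.0, FA=300.0, TG=5000.0, Glu=1000.0, G6P=200.0,
    )
    shb = BloodState(Fru=50.0, Glu=1000.0, Pyr=300.0, FA=300.0, TG=1000.0,
                     Ins=1.0, Gcg=1.0)
    sbc = BloodState(Fru=50.0, Glu=1000.0, Pyr=300.0, FA=300.0, TG=1000.0,
                     Ins=1.0, Gcg=1.0)
    return FullState(hepatic, shb, sbc).to_array()


def _clamped(values) -> list[float]:
    # rate-law arguments only; the state itself is never clipped
    return [v if v > 0.0 else 0.0 for v in values]


def assemble_derivatives(
    t_s: float,
    y: np.ndarray,
    params: ParameterSet,
    diet: DietSpec,
    mode: str = "paper-faithful",
) -> np.ndarray:
    """Right-hand side of the 25-state system at time ``t_s`` (seconds).

    Hepatocyte block from the reaction network; hepatic-blood block loses
    ``T * R_HE`` to the hepatocytes and exchanges with the systemic blood
    by circulation; systemic block receives the meals and the periphery
    closures.  Raises :class:`SimulationError` on a non-finite state,
    naming the offending species.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        bad = STATE_NAMES[int(np.argmin(np.isfinite(y)))]
        raise SimulationError(
            f"non-finite state in {bad} at t={t_s / 3600.0:.4f} h",
            t_h=t_s / 3600.0,
            state=y,
        )
    sh = HepaticState(*_clamped(y[:11]))
    shb = BloodState(*_clamped(y[11:18]))
    sbc = BloodState(*_clamped(y[18:25]))

    rates = evaluate_hepatic_rates(sh, params)
    transports = evaluate_transports(shb, sh, params)
    dhep = hepatic_derivatives(rates, transports, mode)

    r_he = params["R_HE"]
    meal_fru, meal_glu = meal_input_rate(diet, t_s / 3600.0)
    use = periphery_fluxes(sbc, params)
    dIns_shb, dGcg_shb, dIns_sbc, dGcg_sbc = hormone_derivatives(
        sbc, shb, params
    )

    out = np.empty(N_STATES)
    out[:11] = dhep
    # hepatic blood: transport drain (scaled by R_HE) plus circulation
    meta_T = (transports.T_Fru, transports.T_Glu, transports.T_Pyr,
              transports.T_FA, transports.T_TG)
    sbc_meal = (meal_fru, meal_glu, 0.0, 0.0, 0.0)
    sbc_closure = (
        0.0,
        -use.USE_Glu - use.UP_FA - use.UP_TG,
        0.0,
        -use.USE_FA + use.UP_FA,
        -use.USE_TG + use.UP_TG,
    )
    for k in range(5):
        shb_term, sbc_term = circulation_pair(sbc[k], shb[k], params)
        out[11 + k] = -meta_T[k] * r_he + shb_term
        out[18 + k] = sbc_meal[k] + sbc_term + sbc_closure[k]
    out[16], out[17] = dIns_shb, dGcg_shb
    out[23], out[24] = dIns_sbc, dGcg_sbc
    return out


@dataclass
class SimulationResult:
    """Sampled trajectory of one integration run."""

    times_h: np.ndarray  # strictly increasing, hours since 08:00
    states: np.ndarray  # shape (n_times, 25), uM / normalised hormone units
    state_names: list[str] = field(default_factory=lambda: list(STATE_NAMES))
    rates: np.ndarray | None = None  # (n_times, 16) hepatic reaction rates
    transports: np.ndarray | None = None  # (n_times, 5)
    config: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, _IDX[name]]

    def endpoint(self, name: str) -> float:
        return float(self.states[-1, _IDX[name]])

    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()

    def to_frame(self, include_fluxes: bool = False):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=self.state_names)
        df.insert(0, "time_h", self.times_h)
        if include_fluxes and self.rates is not None:
            for j, name in enumerate(RateVector._fields):
                df[name] = self.rates[:, j]
            for j, name in enumerate(TransportVector._fields):
                df[name] = self.transports[:, j]
        return df

    def to_csv(self, path, include_fluxes: bool = False) -> None:
        # %.17g round-trips IEEE doubles exactly
        self.to_frame(include_fluxes).to_csv(
            path, index=False, float_format="%.17g"
        )


def run_simulation(
    initial,
    params: ParameterSet,
    diet: DietSpec,
    horizon_h: float = 12.0,
    *,
    t0_h: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    report_dt_min: float = 1.0,
    mode: str = "paper-faithful",
    with_fluxes: bool = False,
) -> SimulationResult:
    """Integrate the model over ``horizon_h`` hours.

    ``initial`` may be a :class:`FullState` or a length-25 array.  The
    trajectory is sampled on a fixed reporting grid (default 1 min);
    integration itself is adaptive.
    """
    if horizon_h <= 0:
        raise ValueError("horizon_h must be > 0")
    if mode not in STOICHIOMETRY_MODES:
        raise ValueError(f"unknown stoichiometry mode {mode!r}")
    y0 = initial.to_array() if isinstance(initial, FullState) else np.asarray(
        initial, dtype=float
    )
    if y0.shape != (N_STATES,):
        raise ValueError(f"initial state must have 25 components, got {y0.shape}")

    def rhs(t, y):
        return assemble_derivatives(t, y, params, diet, mode)

    t0, t1 = t0_h * 3600.0, (t0_h + horizon_h) * 3600.0
    n_report = int(round(horizon_h * 60.0 / report_dt_min)) + 1
    t_eval = np.linspace(t0, t1, n_report)
    sol = solve_ivp(
        rhs, (t0, t1), y0, method=method, t_eval=t_eval, rtol=rtol, atol=atol
    )
    if not sol.success:
        last_t = sol.t[-1] / 3600.0 if sol.t.size else t0_h
        last_y = sol.y[:, -1] if sol.t.size else y0
        raise SimulationError(
            f"solver failed at t={last_t:.4f} h: {sol.message}",
            t_h=last_t,
            state=last_y,
        )
    states = sol.y.T
    result = SimulationResult(
        times_h=sol.t / 3600.0,
        states=states,
        config={
            "diet": diet.name,
            "grams_per_meal": diet.grams_per_meal,
            "fructose_fraction": diet.fructose_fraction,
            "params_version": params.version,
            "stoichiometry_mode": mode,
            "R_BS": params["R_BS"],
            "rtol": rtol,
            "atol": atol,
            "method": method,
            "horizon_h": horizon_h,
            "t0_h": t0_h,
        },
    )
    if with_fluxes:
        n = states.shape[0]
        rmat = np.empty((n, len(RateVector._fields)))
        tmat = np.empty((n, len(TransportVector._fields)))
        for i in range(n):
            sh = HepaticState(*_clamped(states[i, :11]))
            shb = BloodState(*_clamped(states[i, 11:18]))
            rmat[i] = evaluate_hepatic_rates(sh, params)
            tmat[i] = evaluate_transports(shb, sh, params)
        result.rates = rmat
        result.transports = tmat
    return result


# species floors for relative-change tests: metabolites in uM, hormones
# are O(1) dimensionless
_CHANGE_FLOOR = np.array([1.0] * 11 + [1.0] * 5 + [0.01] * 2 + [1.0] * 5 + [0.01] * 2)


def _relative_change(new: np.ndarray, old: np.ndarray) -> float:
    scale = np.maximum(np.abs(old), _CHANGE_FLOOR)
    return float(np.max(np.abs(new - old) / scale))


def run_to_baseline(
    params: ParameterSet,
    diet: DietSpec,
    *,
    mode: str = "paper-faithful",
    tol: float = 1e-3,
    max_days: int = 30,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> np.ndarray:
    """Run-in to the daily periodic orbit; returns the 08:00 state.

    Integrates repeated identical 24-h meal days from the built-in
    cold-start state until the day-over-day maximum relative state change
    drops below ``tol`` (default 0.1%).  Deterministic; raises
    :class:`SimulationError` if the cap is hit.
    """
    state = default_initial_state()
    for _day in range(max_days):
        res = run_simulation(
            state, params, diet, horizon_h=24.0, rtol=rtol, atol=atol,
            method=method, report_dt_min=30.0, mode=mode,
        )
        new = res.final_state()
        if _relative_change(new, state) < tol:
            return new
        state = new
    raise SimulationError(
        f"run-in did not converge within {max_days} days (diet {diet.name!r})"
    )


def find_equilibrium(
    params: ParameterSet,
    *,
    mode: str = "paper-faithful",
    pre_integrate_h: float = 72.0,
) -> np.ndarray:
    """Zero-input algebraic equilibrium by damped root-finding on the RHS.

    Integrates the fasted system long enough to land in the equilibrium's
    basin, then polishes with a Newton-type root solve.  Serves as the
    independent cross-check for the fasted run-in.
    """
    fasted = zero_diet()
    res = run_simulation(
        default_initial_state(), params, fasted,
        horizon_h=pre_integrate_h, report_dt_min=60.0, mode=mode,
    )
    guess = res.final_state()

    def fun(y):
        return assemble_derivatives(0.0, y, params, fasted, mode)

    sol = root(fun, guess, method="hybr", tol=1e-12)
    if sol.success and float(np.max(np.abs(fun(sol.x)))) <= float(
        np.max(np.abs(fun(guess)))
    ):
        return sol.x
    return guess


CARBON_WEIGHTS = {
    "Fru": 6, "F1P": 6, "DHAP": 3, "GA": 3, "GA3P": 3, "Pyr": 3,
    "ACoA": 2, "FA": 16, "TG": 51, "Glu": 6, "G6P": 6,
}

# per-event species changes for each reaction; the lipolysis glyceraldehyde
# return exists only in carbon-consistent mode (see kinetics module)
_REACTION_STOICH: dict[str, dict[str, float]] = {
    "KHK": {"Fru": -1, "F1P": 1},
    "aldB": {"F1P": -1, "DHAP": 1, "GA": 1},
    "TPI_DHAP": {"DHAP": -1, "GA3P": 1},
    "TPI_GA3P": {"GA3P": -1, "DHAP": 1},
    "Tri": {"GA": -1, "GA3P": 1},
    "PK": {"GA3P": -1, "Pyr": 1},
    "PEPCK": {"Pyr": -1, "GA3P": 1},
    "PDC": {"Pyr": -1, "ACoA": 1},  # third carbon leaves as CO2
    "FAS": {"ACoA": -8, "FA": 1},
    "boxi": {"FA": -1, "ACoA": 8},
    "TGS": {"FA": -3, "GA3P": -1, "TG": 1},
    "Lply": {"TG": -1, "FA": 3},  # +GA in carbon-consistent mode
    "GK": {"Glu": -1, "G6P": 1},
    "G6Pase": {"G6P": -1, "Glu": 1},
    # hexose <-> triose interconversion: two trioses per hexose
    "FBP": {"GA3P": -2, "G6P": 1},
    "PFK": {"G6P": -1, "GA3P": 2},
}


def carbon_audit(
    rates: RateVector, mode: str = "paper-faithful"
) -> dict[str, float]:
    """Carbon balance residual per reaction (uM carbon / s).

    Each residual is the carbon-weighted sum of the reaction's species
    changes times its current rate.  Expected non-zero entries: pyruvate
    oxidation loses one carbon per event as CO2 (residual ``-R_PDC``),
    and in paper-faithful mode lipolysis loses the 3-carbon glycerol
    backbone (``-3*R_Lply``) because the source ODE table does not return
    it to the glyceraldehyde pool.
    """
    if mode not in STOICHIOMETRY_MODES:
        raise ValueError(f"unknown stoichiometry mode {mode!r}")
    residuals: dict[str, float] = {}
    for name, stoich in _REACTION_STOICH.items():
        stoich = dict(stoich)
        if name == "Lply" and mode == "carbon-consistent":
            stoich["GA"] = 1
        balance = sum(CARBON_WEIGHTS[sp] * nu for sp, nu in stoich.items())
        rate = getattr(rates, f"R_{name}")
        residuals[name] = balance * rate
    return residuals
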