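"""Meal schedule -> time-dependent carbohydrate input rates.

A meal of ``grams_per_meal`` carbohydrate, split between fructose and
glucose by ``fructose_fraction``, is absorbed into the systemic blood as a
smooth ``sin^6`` pulse over a 4-h window.  Three meals (08:00, 12:00,
16:00 by default) give three non-overlapping pulses per day; outside all
windows the input is zero.  The pulse amplitude is normalised so the
time-integral of each pulse equals the meal dose expressed as a systemic
concentration increment (mean of sin^6 over its period = 5/16).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = ["DietSpec", "meal_amplitude", "meal_input_rate", "scenario_diets"]

SIN6_MEAN = 5.0 / 16.0  # mean of sin^6 over a half-period
HEXOSE_MOLAR_MASS = 180.156  # g/mol, both fructose and glucose
CLOCK_START_H = 8.0  # simulation t=0 corresponds to 08:00


@dataclass(frozen=True)
class DietSpec:
    """One day's carbohydrate intake pattern.

    Parameters
    ----------
    grams_per_meal
        Carbohydrate per meal (g).
    fructose_fraction
        Fraction of the meal that is fructose, in [0, 1]; the rest is
        glucose.
    meal_times
        Clock hours at which meals start.
    window_h
        Absorption window per meal (h); the sin^6 pulse spans exactly one
        window.
    distribution_volume_L
        Volume the dose is diluted into (systemic blood, V_body - V_liver).
    """

    grams_per_meal: float = 100.0
    fructose_fraction: float = 0.5
    meal_times: tuple[float, ...] = (8.0, 12.0, 16.0)
    window_h: float = 4.0
    molar_mass: float = HEXOSE_MOLAR_MASS
    distribution_volume_L: float = 4.2
    name: str = field(default="custom", compare=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.fructose_fraction <= 1.0):
            raise ValueError(
                f"fructose_fraction must lie in [0,1], got {self.fructose_fraction}"
            )
        if self.grams_per_meal < 0:
            raise ValueError("grams_per_meal must be >= 0")
        if self.window_h <= 0:
            raise ValueError("window_h must be > 0")
        if self.distribution_volume_L <= 0:
            raise ValueError("distribution_volume_L must be > 0")
        starts = sorted(self.meal_times)
        for a, b in zip(starts, starts[1:]):
            if b < a + self.window_h:
                raise ValueError(
                    f"meal windows overlap: meals at {a} h and {b} h with "
                    f"{self.window_h}-h windows"
                )

    def dose_concentration(self, species: str) -> float:
        """Per-meal dose of one hexose as a concentration increment (uM)."""
        frac = {
            "fructose": self.fructose_fraction,
            "glucose": 1.0 - self.fructose_fraction,
        }[species]
        grams = self.grams_per_meal * frac
        micromol = grams / self.molar_mass * 1e6
        return micromol / self.distribution_volume_L


def meal_amplitude(spec: DietSpec, species: str) -> float:
    """Peak input rate v_input (uM/s) of one sin^6 absorption pulse.

    Chosen so that ``integral(v_input * sin^6(pi/window * t), one window)``
    equals :meth:`DietSpec.dose_concentration`.
    """
    window_s = spec.window_h * 3600.0
    return spec.dose_concentration(species) / (SIN6_MEAN * window_s)


def meal_input_rate(spec: DietSpec, t_h: float) -> tuple[float, float]:
    """(Meal_Fru, Meal_Glu) input rates (uM/s) at simulation time ``t_h``.

    ``t_h`` is hours since simulation start (t=0 is 08:00); days repeat
    with a 24-h period so multi-day runs see identical meal schedules.
    """
    clock = (t_h + CLOCK_START_H) % 24.0
    shape = 0.0
    for m in spec.meal_times:
        dt = clock - m
        if dt < 0:
            dt += 24.0
        if 0.0 <= dt < spec.window_h:
            shape += math.sin(math.pi / spec.window_h * dt) ** 6
    if shape == 0.0:
        return (0.0, 0.0)
    return (
        meal_amplitude(spec, "fructose") * shape,
        meal_amplitude(spec, "glucose") * shape,
    )


def scenario_diets() -> dict[str, DietSpec]:
    """The named diet presets used by the three study scenarios."""
    presets = {
        "fructose-100g": DietSpec(100.0, 1.0, name="fructose-100g"),
        "mixed-100g": DietSpec(100.0, 0.5, name="mixed-100g"),
        "glucose-100g": DietSpec(100.0, 0.0, name="glucose-100g"),
        "fructose-150g": DietSpec(150.0, 1.0, name="fructose-150g"),
    }
    return presets


def zero_diet() -> DietSpec:
    """A fasted (no-input) diet."""
    return DietSpec(grams_per_meal=0.0, fructose_fraction=0.5, name="fasted")
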