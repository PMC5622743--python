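"""Steady-state energy balance: daily energy-intake change -> weight and BMI.

A sustained change of rho kJ/day in energy intake eventually shifts
steady-state body weight by 1 kg.  For adults the widely used rule of thumb
is rho = 100 kJ/day per kg; children need larger intake changes per kg
because part of the energy differential is absorbed by growth, so the child
coefficients are larger and sex/band specific.  The mapping is linear:
delta_weight = delta_kj / rho, applied from the first model year (the intake
change is sustained for life, so the steady state is used throughout).

BMI changes are a pure location shift: delta_bmi = delta_weight / height^2
with the stratum's mean height; the within-stratum BMI spread is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import age_band


def _default_rho_child() -> dict[tuple[str, str], float]:
    # Back-fitted band-level coefficients (kJ/day per kg).
    return {
        ("male", "2-12"): 195.0,
        ("female", "2-12"): 180.0,
        ("male", "13-19"): 120.0,
        ("female", "13-19"): 103.0,
    }


@dataclass(frozen=True)
class EnergyBalanceParams:
    """Steady-state energy-to-weight coefficients (kJ/day per kg)."""

    rho_adult: float = 100.0
    rho_child: dict[tuple[str, str], float] = field(default_factory=_default_rho_child)
    adult_age_threshold: int = 20

    def __post_init__(self) -> None:
        if self.rho_adult <= 0 or any(v <= 0 for v in self.rho_child.values()):
            raise ValueError("all rho coefficients must be positive")

    def rho(self, sex: str, age: int) -> float:
        if age >= self.adult_age_threshold:
            return self.rho_adult
        return self.rho_child[(sex, age_band(age))]


DEFAULT_PARAMS = EnergyBalanceParams()


def weight_change(delta_kj: float, sex: str = "male", age: int = 25,
                  params: EnergyBalanceParams = DEFAULT_PARAMS) -> float:
    """Steady-state body-weight change (kg) for a sustained intake change."""
    return delta_kj / params.rho(sex, age)


def bmi_change(delta_weight: float, height: float) -> float:
    """BMI change (kg/m^2) from a weight change at a given height (m)."""
    if height <= 0:
        raise ValueError("height must be positive")
    return delta_weight / height**2


def shift_bmi(cohort: pd.DataFrame, delta_bmi) -> pd.DataFrame:
    """Apply a location shift to the population's BMI distribution.

    ``delta_bmi`` may be a scalar or a per-row array aligned with ``cohort``.
    The standard deviation is unchanged; a shift driving any mean
    non-positive is rejected.
    """
    shifted = cohort.copy()
    shifted["bmi_mean"] = shifted["bmi_mean"] + delta_bmi
    if (shifted["bmi_mean"] <= 0).any():
        raise ValueError("BMI shift produces non-positive mean")
    return shifted


def body_shift(energy_change: pd.DataFrame, population: pd.DataFrame,
               params: EnergyBalanceParams = DEFAULT_PARAMS) -> pd.DataFrame:
    """Per (sex, age) weight and BMI changes from a per-age energy change.

    ``energy_change`` needs columns ``sex, age, delta_kj``; heights come from
    the population table.  Returns ``sex, age, delta_kj, delta_weight,
    delta_bmi``.
    """
    merged = energy_change.merge(population[["sex", "age", "mean_height"]],
                                 on=["sex", "age"], how="left", validate="1:1")
    if merged["mean_height"].isna().any():
        raise ValueError("population table missing strata present in energy change")
    rho = np.array([params.rho(s, a) for s, a in zip(merged["sex"], merged["age"])])
    merged["delta_weight"] = merged["delta_kj"] / rho
    merged["delta_bmi"] = merged["delta_weight"] / merged["mean_height"] ** 2
    return merged[["sex", "age", "delta_kj", "delta_weight", "delta_bmi"]]
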