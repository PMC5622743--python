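"""Intervention effect sizes: scenario -> change in mean daily energy intake.

Two interventions are modelled on sugar-sweetened beverages (SSBs):

* **package_cap** — a cap (default 375 mL) on single-serve package sizes.
  For every single-serve package size above the cap, the volume in excess of
  the cap, weighted by that size's share of total SSB volume sold, is removed
  from consumption.  The summed proportional reduction is applied uniformly
  across age-sex strata, scaled by each stratum's SSB energy intake.
  Optional behavioural adjustments: *compensation* (a fraction of the removed
  excess is re-consumed in other formats) and *substitution* (a fraction of
  consumers swap to a 0 kJ alternative).
* **energy_reduction** — reformulation of all SSBs to a lower energy density,
  removing a fixed percentage of SSB energy intake.

Mandatory scenarios assume full industry adherence; voluntary scenarios
assume 20% of eligible products adopt the change.  Effects are assumed
sustained for the lifetime of the population.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .synthetic_data import AGE_BANDS, age_band

VALID_INTERVENTIONS = ("package_cap", "energy_reduction")
SUBSTITUTION_SCOPES = ("all_ssb", "affected_only")


@dataclass(frozen=True)
class Scenario:
    """A single intervention scenario.

    Parameters mirror the modelled scenario grid: A1-A6 are package-cap
    scenarios (mandatory/voluntary x none/compensation/substitution), B1-B4
    are reformulation scenarios (5%/30% x mandatory/voluntary).
    """

    id: str
    intervention: str
    cap: float = 375.0
    kj_reduction: float = 0.0
    mandatory: bool = True
    adherence: float = 1.0
    compensation: float = 0.0
    substitution: float = 0.0
    substitution_scope: str = "all_ssb"

    def __post_init__(self) -> None:
        if self.intervention not in VALID_INTERVENTIONS:
            raise ValueError(f"unknown intervention {self.intervention!r}")
        if not 0 < self.adherence <= 1:
            raise ValueError("adherence must be in (0, 1]")
        if not 0 <= self.kj_reduction <= 1:
            raise ValueError("kj_reduction must be in [0, 1]")
        if not 0 <= self.compensation <= 1 or not 0 <= self.substitution <= 1:
            raise ValueError("compensation/substitution must be in [0, 1]")
        if self.compensation > 0 and self.substitution > 0:
            raise ValueError("compensation and substitution are mutually exclusive")
        if self.intervention == "package_cap" and self.cap <= 0:
            raise ValueError("cap must be positive")
        if self.substitution_scope not in SUBSTITUTION_SCOPES:
            raise ValueError(f"unknown substitution_scope {self.substitution_scope!r}")


def load_scenarios() -> dict[str, Scenario]:
    """Load the immutable default scenario registry (A1-A6, B1-B4)."""
    text = resources.files("ssbcea.data").joinpath("scenarios.yaml").read_text()
    raw = yaml.safe_load(text)
    return {sid: Scenario(id=sid, **params) for sid, params in raw.items()}


def get_scenario(scenario_id: str, **overrides) -> Scenario:
    registry = load_scenarios()
    if scenario_id not in registry:
        raise KeyError(f"unknown scenario id {scenario_id!r}; known: {sorted(registry)}")
    scenario = registry[scenario_id]
    return replace(scenario, **overrides) if overrides else scenario


def _check_shares(shares: pd.DataFrame) -> None:
    total = float(shares["volume_share"].sum())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"volume shares must sum to 1 (got {total:.6f})")
    if (shares["volume_share"] < 0).any():
        raise ValueError("volume shares must be non-negative")


def excess_volume_fraction(shares: pd.DataFrame, cap: float = 375.0) -> float:
    """Fraction of total SSB volume sold that lies above the cap.

    For each single-serve package size s > cap this is volume_share(s) x
    (s - cap) / s, summed over sizes: the share-weighted proportion of each
    affected package that the cap removes.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    _check_shares(shares)
    affected = shares[shares["single_serve"] & (shares["package_size"] > cap)]
    sizes = affected["package_size"].to_numpy(dtype=float)
    weights = affected["volume_share"].to_numpy(dtype=float)
    return float(np.sum(weights * (sizes - cap) / sizes))


def affected_volume_share(shares: pd.DataFrame, cap: float = 375.0) -> float:
    """Share of all SSB volume sold in single-serve packages above the cap."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    _check_shares(shares)
    affected = shares[shares["single_serve"] & (shares["package_size"] > cap)]
    return float(affected["volume_share"].sum())


def package_cap_effect(profile: pd.DataFrame, shares: pd.DataFrame,
                       scenario: Scenario) -> pd.DataFrame:
    """Energy-intake change (kJ/day/person) per (sex, age_band) for a cap.

    The proportional energy reduction is::

        f = excess_fraction x (1 - compensation) x (1 - substitution)
            + substitution x substituted_share

    where ``substituted_share`` is 1 under the default ``all_ssb`` reading
    (substituting consumers swap all their SSBs to a 0 kJ alternative) or the
    affected volume share under ``affected_only`` (they swap only the capped
    single-serve products).  The result is scaled by adherence and each
    stratum's SSB energy intake.
    """
    if scenario.intervention != "package_cap":
        raise ValueError("package_cap_effect requires a package_cap scenario")
    excess = excess_volume_fraction(shares, scenario.cap)
    if scenario.substitution_scope == "all_ssb":
        substituted_share = 1.0
    else:
        substituted_share = affected_volume_share(shares, scenario.cap)
    fraction = (excess * (1.0 - scenario.compensation) * (1.0 - scenario.substitution)
                + scenario.substitution * substituted_share)
    out = profile[["sex", "age_band", "ssb_energy"]].copy()
    out["delta_kj"] = -out["ssb_energy"] * fraction * scenario.adherence
    return out[["sex", "age_band", "delta_kj"]]


def energy_reduction_effect(profile: pd.DataFrame, scenario: Scenario) -> pd.DataFrame:
    """Energy-intake change per (sex, age_band) for reformulation.

    A uniform percentage cut of SSB energy intake, scaled by adherence; no
    compensatory drinking is assumed for reformulated products.
    """
    if scenario.intervention != "energy_reduction":
        raise ValueError("energy_reduction_effect requires an energy_reduction scenario")
    if not 0 <= scenario.kj_reduction <= 1:
        raise ValueError("kj_reduction must be in [0, 1]")
    out = profile[["sex", "age_band", "ssb_energy"]].copy()
    out["delta_kj"] = -out["ssb_energy"] * scenario.kj_reduction * scenario.adherence
    return out[["sex", "age_band", "delta_kj"]]


def apply_scenario(scenario: Scenario, profile: pd.DataFrame,
                   shares: pd.DataFrame) -> pd.DataFrame:
    """Dispatch to the effect model for the scenario's intervention type."""
    if scenario.intervention == "package_cap":
        return package_cap_effect(profile, shares, scenario)
    return energy_reduction_effect(profile, scenario)


def expand_bands(change_bands: pd.DataFrame, ages: np.ndarray | None = None,
                 max_age: int = 100) -> pd.DataFrame:
    """Broadcast a band-level energy change to single-year ages.

    Intake is assumed flat within each band (the survey reports band-level
    means only).  Returns columns ``sex, age, delta_kj``.
    """
    if ages is None:
        ages = np.arange(2, max_age + 1)
    rows = []
    lookup = change_bands.set_index(["sex", "age_band"])["delta_kj"]
    for sex in change_bands["sex"].unique():
        for age in ages:
            rows.append({"sex": sex, "age": int(age),
                         "delta_kj": float(lookup[(sex, age_band(int(age)))])})
    return pd.DataFrame(rows)
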