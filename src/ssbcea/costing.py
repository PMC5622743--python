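"""Intervention cost model: components, payers, uncertainty, time profiles.

Four cost components are modelled (all in millions of 2010 AUD):

* passing legislation (government, gamma-distributed, year 1 only,
  mandatory scenarios only);
* administration/enforcement/monitoring (government, PERT, years 1-5,
  mandatory scenarios only);
* industry packaging and reformulation changes (PERT, years 1-2);
* NGO advocacy and promotion (PERT, years 1-2, all scenarios).

The printed industry and NGO estimates correspond to a 20% industry
adherence level; scenarios at other adherence levels scale these components
proportionally (x5 for mandatory full adherence).  A component's stated mean
is a total spread evenly over its active years; streams are discounted with
year 1 as the reference year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .effects import Scenario

#: Adherence level at which the printed cost estimates were produced.
REFERENCE_ADHERENCE = 0.2


@dataclass(frozen=True)
class DistributionSpec:
    """Uncertainty distribution for a cost parameter.

    Families: ``gamma_mean_ci`` (params: mean, ci_low, ci_high),
    ``pert_pct_range`` (params: mode, pct_range), ``point`` (params: value).
    """

    family: str
    params: dict

    def __post_init__(self) -> None:
        if self.family == "gamma_mean_ci":
            m, lo, hi = (self.params[k] for k in ("mean", "ci_low", "ci_high"))
            if not lo < m < hi:
                raise ValueError("gamma CI bounds must bracket the mean")
        elif self.family == "pert_pct_range":
            if self.params["pct_range"] <= 0:
                raise ValueError("PERT range percentage must be positive")
        elif self.family != "point":
            raise ValueError(f"unknown distribution family {self.family!r}")

    def mean(self) -> float:
        if self.family == "gamma_mean_ci":
            return float(self.params["mean"])
        if self.family == "pert_pct_range":
            return float(self.params["mode"])
        return float(self.params["value"])

    def draw(self, rng: np.random.Generator) -> float:
        if self.family == "point":
            return float(self.params["value"])
        if self.family == "gamma_mean_ci":
            m = self.params["mean"]
            sd = (self.params["ci_high"] - self.params["ci_low"]) / 3.92
            shape = (m / sd) ** 2
            scale = sd**2 / m
            return float(rng.gamma(shape, scale))
        mode = self.params["mode"]
        r = self.params["pct_range"]
        lo, hi = mode * (1.0 - r), mode * (1.0 + r)
        # Standard (symmetric) beta-PERT: alpha = beta = 3.
        a = 1.0 + 4.0 * (mode - lo) / (hi - lo)
        b = 1.0 + 4.0 * (hi - mode) / (hi - lo)
        return float(lo + (hi - lo) * rng.beta(a, b))


@dataclass(frozen=True)
class CostComponent:
    name: str
    payer: str  # government | industry | ngo
    mean: float  # AUD millions, 2010
    dist: DistributionSpec
    years_active: frozenset[int]
    mandatory_only: bool = False
    scales_with_adherence: bool = False

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError("component mean must be non-negative")
        if not self.years_active:
            raise ValueError("years_active must be non-empty")


def default_cost_components() -> list[CostComponent]:
    """The default four-component cost set (millions of 2010 AUD)."""
    return [
        CostComponent(
            name="legislation", payer="government", mean=1.0,
            dist=DistributionSpec("gamma_mean_ci",
                                  {"mean": 1.0, "ci_low": 0.9, "ci_high": 1.2}),
            years_active=frozenset({1}), mandatory_only=True),
        CostComponent(
            name="administration_monitoring", payer="government", mean=12.3,
            dist=DistributionSpec("pert_pct_range", {"mode": 12.3, "pct_range": 0.5}),
            years_active=frozenset(range(1, 6)), mandatory_only=True),
        CostComponent(
            name="industry_packaging_reformulation", payer="industry", mean=36.9,
            dist=DistributionSpec("pert_pct_range", {"mode": 36.9, "pct_range": 0.5}),
            years_active=frozenset({1, 2}), scales_with_adherence=True),
        CostComponent(
            name="ngo_advocacy", payer="ngo", mean=5.5,
            dist=DistributionSpec("pert_pct_range", {"mode": 5.5, "pct_range": 0.5}),
            years_active=frozenset({1, 2}), scales_with_adherence=True),
    ]


def draw_component(component: CostComponent, rng: np.random.Generator) -> float:
    """Sample one realisation of a component's total cost (AUD millions)."""
    return component.dist.draw(rng)


def scenario_cost(scenario: Scenario, components: list[CostComponent] | None = None,
                  rng: np.random.Generator | None = None,
                  discount_rate: float = 0.03) -> float:
    """Discounted total intervention cost for a scenario (AUD millions).

    Mandatory scenarios include the mandatory-only government components and
    scale adherence-sensitive components up from the printed 20%-adherence
    level (x5 at full adherence).  Voluntary scenarios include only the
    adherence-sensitive components at the printed level.  Pass ``rng`` to
    draw from the uncertainty distributions; omit it for the point (mean)
    estimate.
    """
    if discount_rate < 0:
        raise ValueError("discount rate must be non-negative")
    if components is None:
        components = default_cost_components()
    total = 0.0
    for comp in components:
        if comp.mandatory_only and not scenario.mandatory:
            continue
        value = draw_component(comp, rng) if rng is not None else comp.dist.mean()
        if comp.scales_with_adherence:
            value *= scenario.adherence / REFERENCE_ADHERENCE
        per_year = value / len(comp.years_active)
        for year in comp.years_active:
            total += per_year / (1.0 + discount_rate) ** (year - 1)
    return total
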