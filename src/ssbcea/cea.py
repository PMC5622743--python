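"""Cost-effectiveness assembly: net cost, ICER, dominance, Monte Carlo UIs.

Net cost is the intervention cost plus the (negative) health-care cost
offsets.  An intervention that saves money and gains health is *dominant*
and its ICER is not reported as a ratio; otherwise the ICER (net cost per
HALY gained) is compared against a willingness-to-pay threshold (default
AUD 50,000 per HALY).  Parameter uncertainty is propagated by Monte Carlo
simulation (default 2000 iterations) with percentile (2.5th/97.5th)
uncertainty intervals; one master seed expands to per-iteration substreams
so adding iterations never changes earlier draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_WTP = 50_000.0

DOMINANT = "dominant"
COST_EFFECTIVE = "cost_effective"
NOT_COST_EFFECTIVE = "not_cost_effective"
DOMINATED = "dominated"


def classify(net_cost: float, halys_gained: float,
             wtp: float = DEFAULT_WTP) -> tuple[str, float | None]:
    """Classify an intervention and compute its ICER where defined.

    Cost saving with health gains is dominant (no ICER).  Positive net cost
    with health gains yields an ICER compared (inclusively) against the
    willingness-to-pay threshold.  Costlier and no healthier is dominated;
    the ICER is undefined at zero HALYs.
    """
    if wtp <= 0:
        raise ValueError("willingness-to-pay threshold must be positive")
    if halys_gained > 0:
        if net_cost < 0:
            return DOMINANT, None
        icer = net_cost / halys_gained
        return (COST_EFFECTIVE if icer <= wtp else NOT_COST_EFFECTIVE), icer
    if net_cost > 0:
        return DOMINATED, None
    return NOT_COST_EFFECTIVE, None


def monte_carlo(simulate: Callable[[np.random.Generator], dict],
                n_iterations: int, seed: int) -> pd.DataFrame:
    """Run a seeded Monte Carlo over a one-iteration pipeline callable.

    ``simulate`` receives an independent substream Generator per iteration
    and returns a dict of scalars.  Failed iterations are logged and
    dropped; the returned frame carries the completed draws.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be at least 1")
    streams = np.random.SeedSequence(seed).spawn(n_iterations)
    rows = []
    failures = 0
    for i, stream in enumerate(streams):
        try:
            rows.append(simulate(np.random.default_rng(stream)))
        except Exception:
            failures += 1
            logger.exception("Monte Carlo iteration %d failed", i)
    if failures:
        logger.warning("%d of %d Monte Carlo iterations failed", failures, n_iterations)
    if not rows:
        raise RuntimeError("all Monte Carlo iterations failed")
    return pd.DataFrame(rows)


def _summary(values: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(np.mean(values)),
        "ui_low": float(np.percentile(values, 2.5)),
        "ui_high": float(np.percentile(values, 97.5)),
    }


@dataclass(frozen=True)
class CEAResult:
    """Cost-effectiveness summary for one scenario (means with 95% UIs)."""

    scenario_id: str
    halys_gained: dict[str, float]
    intervention_cost: dict[str, float]
    cost_offsets: dict[str, float]
    net_cost: dict[str, float]
    classification: str
    icer: float | None
    n_iterations: int
    dominant_fraction: float

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario_id,
            "halys_gained": self.halys_gained,
            "intervention_cost_aud_m": self.intervention_cost,
            "cost_offsets_aud_m": self.cost_offsets,
            "net_cost_aud_m": self.net_cost,
            "classification": self.classification,
            "icer_aud_per_haly": self.icer,
            "n_iterations": self.n_iterations,
            "dominant_fraction": self.dominant_fraction,
        }


def summarize(draws: pd.DataFrame, scenario_id: str,
              wtp: float = DEFAULT_WTP) -> CEAResult:
    """Summarise Monte Carlo draws into a CEAResult.

    ``draws`` needs columns ``halys_gained``, ``intervention_cost`` and
    ``cost_offsets`` (offsets negative when the intervention saves costs;
    costs in AUD millions, HALYs in person-years).
    """
    net = draws["intervention_cost"].to_numpy() + draws["cost_offsets"].to_numpy()
    halys = draws["halys_gained"].to_numpy()
    classification, icer = classify(float(net.mean()), float(halys.mean()), wtp)
    dominant_fraction = float(np.mean((net < 0) & (halys > 0)))
    return CEAResult(
        scenario_id=scenario_id,
        halys_gained=_summary(halys),
        intervention_cost=_summary(draws["intervention_cost"].to_numpy()),
        cost_offsets=_summary(draws["cost_offsets"].to_numpy()),
        net_cost=_summary(net),
        classification=classification,
        icer=icer,
        n_iterations=len(draws),
        dominant_fraction=dominant_fraction,
    )


def ce_plane(draws: pd.DataFrame, scenario_id: str | None = None) -> tuple[pd.DataFrame, dict]:
    """Cost-effectiveness plane points and quadrant summary.

    Returns one (incremental cost, incremental HALYs) point per iteration
    and the fraction of draws falling in each quadrant (the south-east
    quadrant — health gained, money saved — is the dominant one).
    """
    if len(draws) < 1:
        raise ValueError("at least one draw is required")
    net = draws["intervention_cost"].to_numpy() + draws["cost_offsets"].to_numpy()
    halys = draws["halys_gained"].to_numpy()
    points = pd.DataFrame({
        "iteration": np.arange(len(draws)),
        "inc_cost_aud_m": net,
        "inc_halys": halys,
    })
    if scenario_id is not None:
        points.insert(0, "scenario", scenario_id)
    summary = {
        "dominant": float(np.mean((net < 0) & (halys > 0))),
        "north_east": float(np.mean((net >= 0) & (halys > 0))),
        "south_west": float(np.mean((net < 0) & (halys <= 0))),
        "north_west": float(np.mean((net >= 0) & (halys <= 0))),
    }
    return points, summary
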