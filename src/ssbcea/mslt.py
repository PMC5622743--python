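"""Proportional multi-state, multiple-cohort life table.

The model follows every single-year-of-age cohort of the baseline population
(ages 2-100, both sexes) over its remaining lifetime in discrete annual
cycles.  Nine obesity-related disease processes run in parallel alongside the
main life table.  Each disease process is a three-state model (susceptible ->
prevalent -> dead-of-disease, with optional remission) driven by annual rates
converted to probabilities via p = 1 - exp(-rate).  The processes are
*proportional*: they are simulated per capita, independent of all-cause
attrition, and feed back into the main table through (i) the difference in
disease-specific mortality between intervention and reference populations,
added to baseline all-cause mortality, and (ii) prevalence-weighted
disability in the health-state weight.

An intervention shifts the BMI distribution, which scales disease incidence
through a potential impact fraction (PIF).  Two PIF forms are provided: a
mean-shift log-linear form, ``pif = 1 - rr**delta_bmi``, and numerical
integration of the relative-risk curve over a lognormal BMI distribution and
its location-shifted counterpart.

Person-years use a half-cycle correction; cohorts reaching the terminal age
contribute one closing year.  Benefits and costs are discounted to
simulation year 0 (the baseline year).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import SEXES, DiseaseSpec

__all__ = [
    "potential_impact_fraction", "pif_table", "adjust_incidence",
    "run_disease_process", "run_lifetable", "compare_populations",
    "discount", "LifetableOutput", "ComparisonResult",
]


def potential_impact_fraction(rr_per_bmi_unit: float, delta_bmi: float,
                              bmi_mean: float | None = None,
                              bmi_sd: float | None = None,
                              method: str = "mean_shift") -> float:
    """Proportional change in disease incidence from a BMI shift.

    ``mean_shift`` applies the log-linear relative risk to the mean shift:
    ``pif = 1 - rr**delta_bmi`` (a negative shift with rr > 1 gives a
    positive PIF, i.e. an incidence reduction).  ``integral`` evaluates
    ``(E[rr**X] - E[rr**X']) / E[rr**X]`` with X lognormal (moments
    ``bmi_mean``, ``bmi_sd``) and X' the same distribution location-shifted
    by ``delta_bmi``.
    """
    if rr_per_bmi_unit <= 0:
        raise ValueError("relative risk must be positive")
    if method == "mean_shift":
        return 1.0 - rr_per_bmi_unit ** delta_bmi
    if method != "integral":
        raise ValueError(f"unknown PIF method {method!r}")
    if bmi_mean is None or bmi_sd is None:
        raise ValueError("integral method requires bmi_mean and bmi_sd")
    if bmi_mean <= 0 or bmi_sd < 0 or bmi_mean + delta_bmi <= 0:
        raise ValueError("invalid BMI distribution parameters")
    if bmi_sd / bmi_mean < 1e-4:
        # Degenerate distribution: integral collapses to the mean-shift form.
        return 1.0 - rr_per_bmi_unit ** delta_bmi
    x = np.linspace(5.0, 90.0, 4096)
    log_rr = np.log(rr_per_bmi_unit)

    def mean_rr(mean: float) -> float:
        sigma2 = np.log1p((bmi_sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        pdf = np.exp(-(np.log(x) - mu) ** 2 / (2 * sigma2)) / (
            x * np.sqrt(2 * np.pi * sigma2))
        return float(np.trapezoid(np.exp(log_rr * x) * pdf, x))

    base = mean_rr(bmi_mean)
    shifted = mean_rr(bmi_mean + delta_bmi)
    return (base - shifted) / base


def pif_table(diseases: list[DiseaseSpec], shift: pd.DataFrame,
              population: pd.DataFrame, method: str = "mean_shift") -> pd.DataFrame:
    """PIF per (disease, sex, age) from a per-stratum BMI shift.

    ``shift`` needs columns ``sex, age, delta_bmi``; the population table
    supplies the BMI distribution moments for the integral method.
    """
    merged = shift.merge(population[["sex", "age", "bmi_mean", "bmi_sd"]],
                         on=["sex", "age"], how="left", validate="1:1")
    rows = []
    for disease in diseases:
        rr = disease.rates["rr_per_bmi_unit"]
        for rec in merged.itertuples(index=False):
            pif = potential_impact_fraction(
                float(rr[(rec.sex, rec.age)]), rec.delta_bmi,
                bmi_mean=rec.bmi_mean, bmi_sd=rec.bmi_sd, method=method)
            rows.append({"disease": disease.name, "sex": rec.sex,
                         "age": rec.age, "pif": pif})
    return pd.DataFrame(rows)


def adjust_incidence(incidence, pif):
    """Scale incidence by (1 - PIF); a PIF of 1 or more is rejected."""
    pif_arr = np.asarray(pif, dtype=float)
    if (pif_arr >= 1.0).any():
        raise ValueError("PIF must be below 1")
    inc = np.asarray(incidence, dtype=float)
    if (inc < 0).any():
        raise ValueError("incidence must be non-negative")
    out = inc * (1.0 - pif_arr)
    return float(out) if np.isscalar(incidence) else out


def _rate_to_prob(rate):
    p = -np.expm1(-np.asarray(rate, dtype=float))
    if (p < 0).any() or (p > 1).any():
        raise ValueError("derived transition probability outside [0, 1]")
    return p


def _disease_step(S, C, D, p_inc, p_cf, p_rem):
    """One annual cycle of the three-state disease process.

    Competing events within the prevalent state: death first, then remission.
    Returns updated states and the deaths incurred this cycle.  Mass is
    conserved: S + C + D is invariant.
    """
    deaths = C * p_cf
    S_new = S * (1.0 - p_inc) + C * (1.0 - p_cf) * p_rem
    C_new = C * (1.0 - p_cf) * (1.0 - p_rem) + S * p_inc
    return S_new, C_new, D + deaths, deaths


def run_disease_process(disease: DiseaseSpec, sex: str, entry_age: int,
                        count: float = 1.0, max_age: int = 100,
                        incidence: np.ndarray | None = None,
                        n_years: int | None = None) -> pd.DataFrame:
    """Simulate one disease process for a single cohort.

    The cohort enters at ``entry_age`` with the disease's prevalence at that
    age already prevalent, and is followed in annual cycles to ``max_age``
    (or ``n_years`` cycles if given).  ``incidence`` optionally overrides the
    disease's incidence rates (e.g. PIF-adjusted), indexed by age like the
    rates table.  Returns per-year counts of susceptible, prevalent and
    cumulative dead-of-disease persons.
    """
    rates = disease.rates.xs(sex, level="sex")
    ages = rates.index.to_numpy()
    if entry_age not in ages:
        raise ValueError(f"entry age {entry_age} not covered by rates table")
    inc = rates["incidence"].to_numpy() if incidence is None else np.asarray(incidence, float)
    cf = rates["case_fatality"].to_numpy()
    rem = rates["remission"].to_numpy()
    start = int(np.searchsorted(ages, entry_age))
    steps = min(max_age - entry_age, n_years if n_years is not None else 10**9)

    C = float(rates["prevalence"].iloc[start]) * count
    S = count - C
    D = 0.0
    records = [{"year": 0, "age": entry_age, "susceptible": S, "prevalent": C, "dead": D}]
    for t in range(steps):
        k = start + t
        S, C, D, _ = _disease_step(S, C, D, _rate_to_prob(inc[k]),
                                   _rate_to_prob(cf[k]), _rate_to_prob(rem[k]))
        records.append({"year": t + 1, "age": entry_age + t + 1,
                        "susceptible": S, "prevalent": C, "dead": D})
    return pd.DataFrame(records)


@dataclass
class LifetableOutput:
    """Aggregate output of one life-table run."""

    life_years: float
    halys: float
    life_years_discounted: float
    halys_discounted: float
    health_costs_discounted: float
    deaths_by_disease: dict[str, float]
    discount_rate: float
    per_year: pd.DataFrame = field(repr=False)
    # Internals kept for population comparison / intervention runs:
    _disease_mortality: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _structure: dict[str, tuple] = field(default_factory=dict, repr=False)


def _prepare_rates(population: pd.DataFrame, diseases: list[DiseaseSpec], sex: str):
    pop = population[population["sex"] == sex].sort_values("age")
    ages = pop["age"].to_numpy()
    if not np.array_equal(ages, np.arange(ages.min(), ages.max() + 1)):
        raise ValueError(f"population ages must be contiguous single years ({sex})")
    tables = []
    for d in diseases:
        r = d.rates.xs(sex, level="sex").reindex(ages)
        if r.isna().any().any():
            raise ValueError(f"{d.name}: rates missing for some ages ({sex})")
        tables.append(r)
    return pop, ages, tables


def run_lifetable(population: pd.DataFrame, diseases: list[DiseaseSpec],
                  pif: pd.DataFrame | None = None,
                  discount_rate: float = 0.03, max_age: int = 100,
                  reference: LifetableOutput | None = None) -> LifetableOutput:
    """Run the proportional multi-state life table for all cohorts.

    With ``pif`` None this is a reference (baseline) run: baseline all-cause
    mortality is used unchanged.  With ``pif`` given, disease incidence is
    scaled by (1 - PIF) and all-cause mortality becomes baseline plus the
    difference in disease-specific mortality relative to ``reference`` (the
    baseline run; computed internally when not supplied).
    """
    if discount_rate < 0:
        raise ValueError("discount rate must be non-negative")
    if pif is not None and reference is None:
        reference = run_lifetable(population, diseases, pif=None,
                                  discount_rate=discount_rate, max_age=max_age)
    pif_lookup = None
    if pif is not None:
        pif_lookup = pif.set_index(["disease", "sex", "age"]).sort_index()["pif"]

    n_dis = len(diseases)
    dw = np.array([d.disability_weight for d in diseases])
    cost_per_case = np.array([d.annual_cost_per_case for d in diseases])

    totals = dict(ly=0.0, haly=0.0, ly_d=0.0, haly_d=0.0, cost_d=0.0)
    deaths = np.zeros(n_dis)
    per_year_rows = []
    disease_mortality: dict[str, np.ndarray] = {}
    structure: dict[str, tuple] = {}

    for sex in SEXES:
        pop, ages, rate_tables = _prepare_rates(population, diseases, sex)
        n_coh = len(ages)
        n_steps = int(max_age - ages.min() + 1)
        entry = ages.copy()
        counts = pop["count"].to_numpy(dtype=float)
        q_base_by_age = pop["mortality_rate"].to_numpy(dtype=float)
        morb_by_age = pop["morbidity_rate"].to_numpy(dtype=float)
        structure[sex] = (tuple(entry), tuple(counts))

        def stacked(col: str) -> np.ndarray:
            if not rate_tables:
                return np.zeros((0, n_coh))
            return np.stack([r[col].to_numpy() for r in rate_tables])

        inc = stacked("incidence")
        cf = stacked("case_fatality")
        rem = stacked("remission")
        prev0 = stacked("prevalence")
        if pif_lookup is not None:
            pif_arr = np.stack([
                pif_lookup.loc[d.name, sex].reindex(ages).to_numpy()
                for d in diseases])
            if np.isnan(pif_arr).any():
                raise ValueError("PIF table missing strata")
            inc = adjust_incidence(inc, pif_arr)
        m_ref = reference._disease_mortality[sex] if reference is not None else None
        m_out = np.zeros((n_dis, n_coh, n_steps))

        # Per-capita disease states per (disease, cohort); cohort i enters at
        # ages[i], so prev0[:, i] is exactly its entry prevalence.
        C = prev0.copy()
        S = 1.0 - C
        D = np.zeros_like(C)
        l = np.ones(n_coh)

        for t in range(n_steps):
            age = entry + t
            active = age <= max_age
            if not active.any():
                break
            idx = np.clip(age - ages.min(), 0, n_coh - 1)
            closing = age == max_age
            stepping = active & ~closing

            alive_in_process = S + C
            pc = np.divide(C, alive_in_process, out=np.zeros_like(C),
                           where=alive_in_process > 0)
            w = 1.0 - morb_by_age[idx] - (dw[:, None] * pc).sum(axis=0)
            if (w[active] < 0).any() or (w[active] > 1).any():
                raise ValueError("health-state weight outside [0, 1]")

            p_inc = _rate_to_prob(np.take(inc, idx, axis=1))
            p_cf = _rate_to_prob(np.take(cf, idx, axis=1))
            p_rem = _rate_to_prob(np.take(rem, idx, axis=1))
            deaths_frac = C * p_cf
            m_d = np.divide(deaths_frac, alive_in_process,
                            out=np.zeros_like(C), where=alive_in_process > 0)
            m_out[:, :, t] = m_d

            q = q_base_by_age[idx].copy()
            if m_ref is not None:
                q = q + (m_d - m_ref[:, :, t]).sum(axis=0)
                q = np.clip(q, 0.0, 1.0)

            l_next = np.where(stepping, l * (1.0 - q), 0.0)
            L = np.where(stepping, 0.5 * (l + l_next) * counts, 0.0)
            L = np.where(closing, l * counts, L)  # terminal-age closing year

            df = 1.0 / (1.0 + discount_rate) ** t
            ly_t = float(L.sum())
            haly_t = float((w * L).sum())
            cost_t = float(((cost_per_case[:, None] * pc).sum(axis=0) * L).sum())
            totals["ly"] += ly_t
            totals["haly"] += haly_t
            totals["ly_d"] += df * ly_t
            totals["haly_d"] += df * haly_t
            totals["cost_d"] += df * cost_t
            deaths += (m_d * np.where(stepping, l * counts, 0.0)).sum(axis=1)
            per_year_rows.append({"sex": sex, "year": t, "life_years": ly_t,
                                  "halys": haly_t, "health_costs": cost_t})

            S, C, D, _ = _disease_step(S, C, D, p_inc, p_cf, p_rem)
            l = l_next

        disease_mortality[sex] = m_out

    return LifetableOutput(
        life_years=totals["ly"], halys=totals["haly"],
        life_years_discounted=totals["ly_d"], halys_discounted=totals["haly_d"],
        health_costs_discounted=totals["cost_d"],
        deaths_by_disease={d.name: float(v) for d, v in zip(diseases, deaths)},
        discount_rate=discount_rate,
        per_year=pd.DataFrame(per_year_rows),
        _disease_mortality=disease_mortality,
        _structure=structure,
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Intervention-minus-reference differences of discounted streams."""

    halys_gained: float
    halys_gained_undiscounted: float
    cost_offsets: float  # negative = health-care savings
    deaths_averted_by_disease: dict[str, float]


def compare_populations(reference: LifetableOutput,
                        intervention: LifetableOutput) -> ComparisonResult:
    """Compare an intervention run against its reference run.

    Both runs must share cohort structure and discount rate.  HALYs gained
    are intervention minus reference; cost offsets are carried as negative
    values when the intervention saves health-care costs.
    """
    if reference._structure != intervention._structure:
        raise ValueError("mismatched cohort structure between populations")
    if reference.discount_rate != intervention.discount_rate:
        raise ValueError("mismatched discount rates")
    averted = {name: reference.deaths_by_disease[name] - intervention.deaths_by_disease[name]
               for name in reference.deaths_by_disease}
    return ComparisonResult(
        halys_gained=intervention.halys_discounted - reference.halys_discounted,
        halys_gained_undiscounted=intervention.halys - reference.halys,
        cost_offsets=intervention.health_costs_discounted - reference.health_costs_discounted,
        deaths_averted_by_disease=averted,
    )


def discount(stream, rate: float, reference_year: int = 0,
             years=None) -> float:
    """Present value of an annual stream at the given discount rate."""
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    values = np.asarray(stream, dtype=float)
    if years is None:
        years = np.arange(len(values))
    years = np.asarray(years, dtype=float)
    return float(np.sum(values / (1.0 + rate) ** (years - reference_year)))
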