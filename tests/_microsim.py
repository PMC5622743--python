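"""Individual-level stochastic oracles for the deterministic life table.

These simulate explicit persons with the same annual rates as the
deterministic model and serve as independent cross-checks: the deterministic
outputs must match the microsimulation means within Monte Carlo error.
"""

from __future__ import annotations

import numpy as np


def microsim_disease_counts(incidence, case_fatality, remission,
                            init_prevalence: float, n_people: int,
                            n_years: int, seed: int):
    """Simulate one disease process for ``n_people`` individuals.

    ``incidence``/``case_fatality``/``remission`` are per-year rate arrays of
    length ``n_years``.  Returns (susceptible, prevalent, dead) counts per
    year (year 0 = entry) as arrays of shape (n_years + 1,), plus the
    per-person final-state array for standard-error estimation.
    """
    rng = np.random.default_rng(seed)
    # 0 = susceptible, 1 = prevalent, 2 = dead of disease
    state = (rng.random(n_people) < init_prevalence).astype(np.int8)
    counts = np.zeros((n_years + 1, 3))
    counts[0] = np.bincount(state, minlength=3)
    for t in range(n_years):
        p_i = -np.expm1(-incidence[t])
        p_f = -np.expm1(-case_fatality[t])
        p_r = -np.expm1(-remission[t])
        u = rng.random(n_people)
        v = rng.random(n_people)
        new_state = state.copy()
        sus = state == 0
        prev = state == 1
        new_state[sus & (u < p_i)] = 1
        dies = prev & (u < p_f)
        remits = prev & ~dies & (v < p_r)
        new_state[dies] = 2
        new_state[remits] = 0
        state = new_state
        counts[t + 1] = np.bincount(state, minlength=3)
    return counts, state


def microsim_lifetable(population, diseases, n_per_cohort: int, seed: int,
                       max_age: int = 100):
    """Individual-level analogue of the proportional life table.

    Only valid as an exact expectation match when every disease has zero
    case fatality (then the proportional disease processes decouple from
    vital status and prevalence among the living equals the per-capita
    prevalent fraction).  Persons contribute one year when surviving a
    cycle, half a year when dying in it, and one closing year at the
    terminal age; health-state weights use start-of-year states.

    Returns per-person arrays (life_years, halys) pooled over cohorts with
    cohort counts as weights, as (values_ly, values_haly, weights).
    """
    rng = np.random.default_rng(seed)
    ly_all, haly_all, w_all = [], [], []
    for sex in population["sex"].unique():
        pop = population[population["sex"] == sex].sort_values("age")
        ages = pop["age"].to_numpy()
        for row in pop.itertuples(index=False):
            if row.count <= 0:
                continue
            entry = int(row.age)
            n = n_per_cohort
            alive = np.ones(n, dtype=bool)
            states = []
            for d in diseases:
                rates = d.rates.xs(sex, level="sex")
                prev0 = float(rates.loc[entry, "prevalence"])
                states.append((rng.random(n) < prev0).astype(np.int8))
            ly = np.zeros(n)
            haly = np.zeros(n)
            for t in range(max_age - entry + 1):
                age = entry + t
                prow = pop[pop["age"] == age].iloc[0]
                w = np.full(n, 1.0 - prow.morbidity_rate)
                for d, st in zip(diseases, states):
                    w -= d.disability_weight * (st == 1)
                if age == max_age:
                    ly += alive * 1.0
                    haly += alive * w
                    break
                q = prow.mortality_rate
                dies = alive & (rng.random(n) < q)
                ly += alive * np.where(dies, 0.5, 1.0)
                haly += alive * np.where(dies, 0.5, 1.0) * w
                alive = alive & ~dies
                for k, d in enumerate(diseases):
                    rates = d.rates.xs(sex, level="sex")
                    p_i = -np.expm1(-float(rates.loc[age, "incidence"]))
                    p_r = -np.expm1(-float(rates.loc[age, "remission"]))
                    st = states[k]
                    u = rng.random(n)
                    st_new = st.copy()
                    st_new[(st == 0) & (u < p_i)] = 1
                    st_new[(st == 1) & (u < p_r)] = 0
                    states[k] = st_new
            ly_all.append(ly)
            haly_all.append(haly)
            w_all.append(np.full(n, row.count / n))
    return (np.concatenate(ly_all), np.concatenate(haly_all),
            np.concatenate(w_all))
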