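import numpy as np
import pandas as pd
import pytest

import ssbcea
from ssbcea.mslt import (adjust_incidence, compare_populations, discount,
                         pif_table, potential_impact_fraction,
                         run_disease_process, run_lifetable)
from ssbcea.synthetic_data import SEXES, DiseaseSpec

from _microsim import microsim_disease_counts, microsim_lifetable


def make_disease(name="toy", incidence=0.0, case_fatality=0.0, remission=0.0,
                 prevalence=0.0, dw=0.0, cost=0.0, rr=1.0,
                 ages=range(2, 101)) -> DiseaseSpec:
    frames = []
    for sex in SEXES:
        frames.append(pd.DataFrame({
            "sex": sex, "age": list(ages),
            "incidence": incidence, "prevalence": prevalence,
            "case_fatality": case_fatality, "remission": remission,
            "rr_per_bmi_unit": rr,
        }))
    rates = pd.concat(frames, ignore_index=True).set_index(["sex", "age"])
    return DiseaseSpec(name=name, disability_weight=dw,
                       annual_cost_per_case=cost, rates=rates)


def make_population(age_lo=60, age_hi=100, counts=None, mortality=0.1,
                    morbidity=0.0):
    """Contiguous-age toy population; ``counts`` maps male entry age -> count."""
    counts = counts or {}
    rows = []
    for sex in SEXES:
        for age in range(age_lo, age_hi + 1):
            q = mortality if np.isscalar(mortality) else mortality(age)
            rows.append({"sex": sex, "age": age,
                         "count": float(counts.get(age, 0)) if sex == "male" else 0.0,
                         "mortality_rate": q, "morbidity_rate": morbidity,
                         "mean_height": 1.7, "mean_weight": 75.0,
                         "bmi_mean": 26.0, "bmi_sd": 4.0})
    return pd.DataFrame(rows)


class TestPotentialImpactFraction:
    def test_zero_shift_gives_zero(self):
        assert potential_impact_fraction(1.2, 0.0) == 0.0

    def test_mean_shift_closed_form(self):
        assert potential_impact_fraction(1.2, -1.0) == pytest.approx(
            1 - 1.2**-1, abs=1e-12)

    def test_integral_collapses_to_mean_shift_for_degenerate_distribution(self):
        ms = potential_impact_fraction(1.2, -0.05)
        integral = potential_impact_fraction(1.2, -0.05, bmi_mean=27.0,
                                             bmi_sd=1e-6, method="integral")
        assert integral == pytest.approx(ms, abs=1e-6)

    def test_integral_close_to_mean_shift_for_realistic_spread(self):
        ms = potential_impact_fraction(1.1, -0.1)
        integral = potential_impact_fraction(1.1, -0.1, bmi_mean=27.0,
                                             bmi_sd=4.0, method="integral")
        assert integral == pytest.approx(ms, rel=0.15)

    def test_sign_opposes_shift(self):
        assert potential_impact_fraction(1.2, -0.5) > 0
        assert potential_impact_fraction(1.2, 0.5) < 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            potential_impact_fraction(0.0, -1.0)
        with pytest.raises(ValueError):
            potential_impact_fraction(1.2, -1.0, method="bogus")


class TestAdjustIncidence:
    def test_identity_and_arithmetic(self):
        assert adjust_incidence(0.01, 0.0) == 0.01
        assert adjust_incidence(0.01, 1 - 1.2**-1) == pytest.approx(0.0083333, abs=1e-6)

    def test_boundary_pif_rejected(self):
        with pytest.raises(ValueError):
            adjust_incidence(0.01, 1.0)
        with pytest.raises(ValueError):
            adjust_incidence(-0.01, 0.0)


class TestDiseaseProcess:
    def test_no_incidence_stays_susceptible(self):
        d = make_disease(incidence=0.0)
        traj = run_disease_process(d, "male", 50, count=1000.0)
        assert (traj["susceptible"] == 1000.0).all()
        assert (traj["prevalent"] == 0.0).all()

    def test_geometric_accumulation(self):
        # Incidence rate -ln(0.9) gives an annual transition probability of
        # exactly 0.1; after 3 years 1000 x (1 - 0.9^3) = 271 are prevalent.
        d = make_disease(incidence=-np.log(0.9))
        traj = run_disease_process(d, "male", 50, count=1000.0, n_years=3)
        assert traj["prevalent"].iloc[-1] == pytest.approx(271.0, abs=1e-9)

    def test_conservation(self):
        d = make_disease(incidence=0.05, case_fatality=0.1, remission=0.02,
                         prevalence=0.2)
        traj = run_disease_process(d, "female", 40, count=1234.5)
        totals = traj[["susceptible", "prevalent", "dead"]].sum(axis=1)
        assert np.allclose(totals, 1234.5, rtol=1e-12)

    def test_matches_individual_microsimulation(self):
        n, years = 100_000, 20
        inc, cf, rem, prev0 = 0.05, 0.08, 0.02, 0.2
        d = make_disease(incidence=inc, case_fatality=cf, remission=rem,
                         prevalence=prev0, ages=range(40, 61))
        det = run_disease_process(d, "male", 40, count=float(n), n_years=years)
        counts, _ = microsim_disease_counts(
            np.full(years, inc), np.full(years, cf), np.full(years, rem),
            prev0, n, years, seed=2024)
        for col, k in (("susceptible", 0), ("prevalent", 1), ("dead", 2)):
            p = det[col].iloc[-1] / n
            se = np.sqrt(n * p * (1 - p))
            assert abs(counts[-1, k] - det[col].iloc[-1]) < 3 * se


class TestLifetable:
    def test_life_expectancy_matches_geometric_closed_form(self):
        q = 0.2
        pop = make_population(counts={60: 1000}, mortality=q)
        out = run_lifetable(pop, [], discount_rate=0.0)
        # Half-cycle-corrected LE for constant q is 1/q - 1/2.
        assert out.life_years / 1000 == pytest.approx(1 / q - 0.5, abs=1e-2)
        assert out.halys == out.life_years

    def test_disability_strictly_reduces_halys(self):
        pop = make_population(counts={60: 1000}, mortality=0.05)
        clean = run_lifetable(pop, [])
        sick = run_lifetable(pop, [make_disease(incidence=0.05, prevalence=0.1,
                                                dw=0.2)])
        assert sick.halys < clean.halys
        assert sick.life_years == clean.life_years  # zero case fatality

    def test_halys_never_exceed_life_years(self, bundle, reference):
        assert reference.halys <= reference.life_years
        assert reference.halys_discounted <= reference.life_years_discounted
        assert reference.halys_discounted <= reference.halys

    def test_weight_out_of_bounds_rejected(self):
        pop = make_population(counts={60: 1000}, morbidity=0.5)
        bad = make_disease(incidence=0.2, prevalence=0.9, dw=0.9)
        with pytest.raises(ValueError):
            run_lifetable(pop, [bad])

    def test_non_contiguous_population_rejected(self):
        pop = make_population(counts={60: 1000})
        pop = pop[pop["age"] != 70]
        with pytest.raises(ValueError):
            run_lifetable(pop, [])

    def test_matches_individual_microsimulation_on_toy(self):
        """Deterministic table vs seeded person-level oracle, 3 cohorts x 2
        diseases (zero case fatality, so the proportional processes are the
        exact expectation of the microsimulation)."""
        counts = {60: 1000, 75: 1000, 90: 1000}
        pop = make_population(counts=counts,
                              mortality=lambda a: 0.01 + 0.002 * (a - 60),
                              morbidity=0.1)
        diseases = [
            make_disease("d1", incidence=0.03, remission=0.01, prevalence=0.1,
                         dw=0.2, ages=range(60, 101)),
            make_disease("d2", incidence=0.01, remission=0.0, prevalence=0.05,
                         dw=0.15, ages=range(60, 101)),
        ]
        det = run_lifetable(pop, diseases, discount_rate=0.0)
        n = 20_000
        ly, haly, w = microsim_lifetable(pop, diseases, n_per_cohort=n, seed=7)
        for det_total, values in ((det.life_years, ly), (det.halys, haly)):
            chunks = values.reshape(len(counts), n)
            weights = np.array(list(counts.values()))
            sim_total = float((weights * chunks.mean(axis=1)).sum())
            se = float(np.sqrt(np.sum(weights**2 * chunks.var(axis=1, ddof=1) / n)))
            assert abs(det_total - sim_total) < 3 * se


class TestComparison:
    def test_null_intervention_gives_exact_zeros(self, bundle, reference):
        zero_shift = bundle.population[["sex", "age"]].assign(delta_bmi=0.0)
        pif = pif_table(bundle.diseases, zero_shift, bundle.population)
        assert (pif["pif"] == 0.0).all()
        out = run_lifetable(bundle.population, bundle.diseases, pif=pif,
                            reference=reference)
        result = compare_populations(reference, out)
        assert result.halys_gained == 0.0
        assert result.cost_offsets == 0.0
        assert all(v == 0.0 for v in result.deaths_averted_by_disease.values())

    def test_gains_monotone_in_bmi_shift(self, bundle, reference):
        def gain(delta):
            shift = bundle.population[["sex", "age"]].assign(delta_bmi=delta)
            pif = pif_table(bundle.diseases, shift, bundle.population)
            out = run_lifetable(bundle.population, bundle.diseases, pif=pif,
                                reference=reference)
            return compare_populations(reference, out)
        small, large = gain(-0.05), gain(-0.15)
        assert 0 < small.halys_gained < large.halys_gained
        assert large.cost_offsets < small.cost_offsets < 0

    def test_discounted_gains_below_undiscounted(self, bundle, reference):
        shift = bundle.population[["sex", "age"]].assign(delta_bmi=-0.1)
        pif = pif_table(bundle.diseases, shift, bundle.population)
        out = run_lifetable(bundle.population, bundle.diseases, pif=pif,
                            reference=reference)
        result = compare_populations(reference, out)
        assert 0 < result.halys_gained < result.halys_gained_undiscounted

    def test_mismatched_structures_rejected(self, bundle, reference):
        other = run_lifetable(make_population(counts={60: 10}), [])
        with pytest.raises(ValueError):
            compare_populations(reference, other)

    def test_largest_mortality_benefit_matches_largest_rr_weighted_burden(
            self, bundle, reference):
        """The disease with the largest RR-weighted fatal burden should show
        the largest deaths averted (ischaemic heart disease here)."""
        shift = bundle.population[["sex", "age"]].assign(delta_bmi=-0.1)
        pif = pif_table(bundle.diseases, shift, bundle.population)
        out = run_lifetable(bundle.population, bundle.diseases, pif=pif,
                            reference=reference)
        averted = compare_populations(reference, out).deaths_averted_by_disease
        burdens = {}
        counts = bundle.population.set_index(["sex", "age"])["count"]
        for d in bundle.diseases:
            r = d.rates
            burdens[d.name] = float((counts * r["incidence"] * r["case_fatality"]
                                     * (r["rr_per_bmi_unit"] - 1)).sum())
        assert max(averted, key=averted.get) == max(burdens, key=burdens.get)
        assert max(averted, key=averted.get) == "ischaemic heart disease"


class TestDiscount:
    def test_zero_rate_is_simple_sum(self):
        assert discount([10, 20, 30], 0.0) == 60.0

    def test_two_year_example(self):
        assert discount([100, 100], 0.03) == pytest.approx(197.087, abs=1e-3)

    def test_payment_in_reference_year(self):
        assert discount([42.0], 0.03) == 42.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount([1.0], -0.01)
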