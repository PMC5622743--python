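# Methods

## Scope and design

`ssbcea` estimates lifetime health and economic consequences of two
sugar-sweetened-beverage (SSB) portion-size interventions — a 375 mL cap on
single-serve packages and reformulation to a 5%/30% lower energy density —
for a closed population aged 2–100, compared against a no-intervention
reference in which the BMI distribution stays unchanged. The pipeline is
deterministic given its inputs; parameter uncertainty enters only through
declared distributions in a seeded Monte Carlo.

## Effect sizes

SSB intake is carried at three age bands (2–12, 13–19, ≥20) by sex, matching
the resolution of the survey tables the model emulates, and broadcast flat
to single-year ages. For the cap, each single-serve package size `s > cap`
contributes `volume_share(s) × (s − cap)/s` to the removed volume fraction;
the summed fraction applies uniformly to every stratum's SSB energy. The
behavioural adjustments follow the scenario grid:

* *compensation* (A2/A5, 25%): that fraction of the removed excess is
  re-consumed, applied multiplicatively to the excess term only;
* *substitution* (A3/A6, 10%): that fraction of consumers swap to a 0 kJ
  alternative. Whether they swap all their SSBs or only the capped products
  is genuinely open; both readings are implemented
  (`substitution_scope ∈ {all_ssb, affected_only}`) with `all_ssb` as the
  default, which produces the large benefit multiple the substitution
  scenarios are expected to show relative to the base case.
* *voluntary adherence* (A4–A6, B3–B4): 20% of eligible products adopt the
  change; effects scale exactly linearly, so voluntary = 0.2 × mandatory
  per stratum.

Effects are sustained for the remaining lifetime (the interventions change
the food environment permanently), so a single per-stratum `Δkj` applies in
every simulated year.

## Energy balance

A sustained intake change maps to a steady-state weight change,
`Δkg = Δkj/ρ`. Adults (≥20) use ρ = 100 kJ/day per kg; this coefficient
reproduces all four published adult energy→weight cells at two-decimal
rounding. Child coefficients were back-fitted per sex and band to the
published child cells: 2–12 male 195, 2–12 female 180, 13–19 male 120,
13–19 female 103 kJ/day per kg (a single 2–12 coefficient cannot fit both
sexes' printed cells; the feasible intervals are disjoint). The steady state
is applied from year 1 — no dynamic weight trajectory is modelled. BMI
shifts are location shifts at the stratum mean height: the within-stratum
BMI spread is unchanged.

## Life table

The multi-state life table runs annual cycles with half-cycle-corrected
person-years; a cohort reaching the terminal age (100) contributes one
closing year. Rates convert to probabilities as `p = 1 − e^{−rate}`, with
guards rejecting anything outside [0, 1]. Each of the nine disease
processes is *proportional*: simulated per capita, independent of all-cause
attrition (so susceptible + prevalent + cumulative disease deaths is
conserved to machine precision), with competing prevalent-state events
ordered death-then-remission within a cycle.

The potential impact fraction defaults to the mean-shift log-linear form
`PIF = 1 − RR^ΔBMI`; a numerical-integration alternative over a lognormal
BMI distribution (right-skewed, as population BMI is) and its shifted
counterpart is available via `pif_method="integral"`, and collapses to the
mean-shift form as the BMI spread goes to zero. PIFs are computed per
(disease, sex, current age), so a cohort ageing across a band boundary picks
up the destination band's shift. Relative risks apply to incidence only,
not case fatality.

Intervention all-cause mortality is baseline mortality plus the summed
difference in disease-specific mortality against the reference run; the
reference run therefore reproduces baseline survival exactly, and a null
intervention yields exactly zero HALY and cost differences (identical
floating-point paths). Health-state weights are
`1 − background morbidity − Σ disability_weight × prevalence-among-process-
survivors`, and prevalent cases accrue each disease's annual health-care
cost. Benefits and costs discount at 3%/yr to simulation year 0. A hook for
a BMI-related quality-of-life decrement independent of the nine diseases is
deliberately absent: no parameters for it are published.

## Intervention costs

Four components (millions of 2010 AUD): legislation (1.0, gamma fitted to
mean 1.0 with 95% CI ≈ 0.9–1.2, year 1, mandatory only), administration and
monitoring (12.3, PERT ±50%, years 1–5, mandatory only), industry packaging
and reformulation (36.9, PERT ±50%, years 1–2), NGO advocacy (5.5, PERT
±50%, years 1–2, all scenarios). The printed industry/NGO estimates
correspond to a 20% adherence level; components flagged
`scales_with_adherence` scale by `adherence/0.2` (×5 for mandatory). Stated
means are totals spread evenly across active years and discounted with year
1 as the cost reference year. The published totals (209.7 M mandatory,
44.5 M voluntary) cannot be reconstructed exactly from the published
component table under any single aggregation rule; this default rule yields
≈222 M and ≈42 M, inside the published 95% uncertainty intervals, which is
the validation applied. The gamma is parameterised by moment matching
(sd = CI width/3.92), so its quantiles approximate, not reproduce, the
slightly asymmetric printed CI.

## Uncertainty analysis

2000 Monte Carlo iterations by default; one master seed spawns independent
per-iteration substreams, so results are bit-reproducible and extending the
iteration count never changes earlier draws. Uncertainty intervals are
non-parametric 2.5th/97.5th percentiles. By default only the cost
distributions are sampled (the published account does not enumerate which
effect parameters were varied); the deterministic epidemiological chain is
then computed once and reused. `sample_effects=True` adds a truncated-normal
multiplier (mean 1, sd 0.2) on the energy-intake change and re-runs the life
table per iteration. Classification: cost saving with health gains is
dominant; otherwise the ICER is compared inclusively against AUD
50,000/HALY.

## Synthetic data

The generator emulates three input bundles the original analysis drew from
national sources:

* **population** — single-year ages 2–100 by sex: cohort sizes (~285k/year,
  tapering after 55), Gompertz–Makeham mortality (monotone beyond mid-life),
  age-increasing background morbidity, growth-curve heights and BMI moments.
  Per-sex multiplicative jitter keeps curves smooth and monotonicity intact.
* **diseases** — the nine obesity-related diseases with logistic age curves
  for incidence and case fatality, quasi-steady-state prevalence
  (incidence × duration), zero remission, literature-plausible relative
  risks per BMI unit (largest for diabetes, 1.18; female-only breast and
  endometrial cancers), disability weights and annual costs per prevalent
  case. Ischaemic heart disease carries the largest RR-weighted fatal
  burden, so it shows the largest mortality benefit, matching the expected
  ranking.
* **consumption** — band-level intakes equal to the published baselines when
  calibrated, with a single energy density of 1.6 kJ/mL (600 kJ ≈ 375 mL);
  package-size shares on a {250, 375, 450, 500, 600, 1250, 2000} mL grid
  (single-serve ≤ 600 mL) calibrated to the 27%/59% marginals.

What the synthetic bundles do **not** emulate: the sales-data-derived excess
volume fraction (the calibrated grid gives 0.041 versus the published
0.026 — the published value is unreachable from any allocation over sizes
≥ 450 mL), true single-year intake profiles within bands, co-morbidity,
incidence trends, and realistic absolute cost levels. Passing tests
therefore demonstrate the correctness and internal consistency of the
machinery — identities, conservation, oracle agreement, orderings — not the
reproduction of the published absolute HALY or cost-offset totals, which
require the unpublished national epidemiology inputs.

## Numerical choices and limitations

* Discrete annual cycles; no within-year event ordering beyond
  death-then-remission; half-cycle person-years.
* Disease prevalence among process survivors weights both disability and
  cost, so background morbidity that already contains some disease burden
  would double-count in levels — differences between populations, the
  quantity of interest, are unaffected.
* Intervention mortality adjustments are clipped to [0, 1] after the
  disease-mortality difference is added (never binding for realistic
  inputs).
* The life-table microsimulation oracle sets case fatality to zero so the
  proportional model is the exact expectation of the individual model;
  nonzero case fatality is cross-checked at the disease-process level, where
  the per-capita process is exactly an independent Markov chain per person.
* Monte Carlo failures in individual iterations are logged and dropped
  rather than aborting the run; the completed count is reported.
* No price/elasticity response, industry revenue loss, equity analysis or
  incidence-trend projection is modelled.
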