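# ssbcea

Cost-effectiveness modelling of portion-size interventions on
sugar-sweetened beverages (SSBs), for health economists and obesity-policy
modellers.

Two population-level interventions are modelled for a closed national
population aged 2–100:

* **package-size cap** — a ban (mandatory or voluntary) on single-serve SSB
  packages larger than 375 mL, with optional compensatory drinking or
  substitution to sugar-free alternatives (scenarios A1–A6);
* **energy reduction** — reformulation of all SSBs to a 5% or 30% lower
  energy density (scenarios B1–B4).

## The model

Each scenario maps to lifetime health and cost outcomes through a fixed
chain:

1. **Effect size.** For the cap, the removed fraction of SSB volume is
   `f = Σ_{s>c} w_s (s − c)/s` over single-serve package sizes `s` above the
   cap `c` with volume shares `w_s`; for reformulation it is the percentage
   energy cut. Both scale each age–sex stratum's SSB energy intake `E` into a
   sustained daily change `Δkj = −E·f·adherence`.
2. **Energy balance.** Steady state: `Δkg = Δkj / ρ` with `ρ = 100` kJ/day
   per kg for adults (larger, band-specific coefficients for children), and
   `ΔBMI = Δkg / h²` at the stratum's mean height.
3. **Proportional multi-state life table.** The BMI shift scales the
   incidence of nine obesity-related diseases via a potential impact
   fraction, `PIF = 1 − RR^ΔBMI`. Each disease runs a
   susceptible → prevalent → dead process in annual cycles
   (`p = 1 − e^{−rate}`); differences in disease mortality perturb all-cause
   survival, and prevalence-weighted disability weights reduce person-years
   to health-adjusted life years (HALYs). Reduced prevalence also yields
   health-care **cost offsets**.
4. **Economics.** Intervention costs (legislation, administration, industry,
   NGO advocacy; gamma/PERT uncertainty) plus cost offsets give net cost;
   `ICER = net cost / HALYs gained` against an AUD 50,000/HALY threshold,
   with cost-saving, health-gaining scenarios classified *dominant*.
   Monte Carlo simulation (2000 iterations, percentile 95% uncertainty
   intervals) propagates parameter uncertainty; all streams are discounted
   at 3%.

The national survey, sales and epidemiology inputs behind the original
analysis are not redistributable; a seeded synthetic generator produces
input bundles with the same structure, calibrated to the published
band-level SSB intakes and package-size marginals (27% of volume
single-serve; 59% of single-serve volume above 375 mL).

## Worked example

```python
from ssbcea import RunConfig, run

config = RunConfig(scenarios=["A1", "B1"], synthetic_seed=1,
                   n_iterations=2000, seed=42, out_dir="out")
results = run(config)
```

On the calibrated synthetic bundle this prints (via `results[...].to_dict()`):

```text
A1 dominant
  halys_gained            339500.6
  intervention_cost_aud_m    222.6 (157.2; 290.6)
  cost_offsets_aud_m       -7060.7
  net_cost_aud_m           -6838.1 (-6903.5; -6770.1)
B1 dominant
  halys_gained            414264.5
  intervention_cost_aud_m    221.4 (158.5; 285.2)
  cost_offsets_aud_m       -8614.7
  net_cost_aud_m           -8393.4 (-8456.3; -8329.5)
```

Both base cases are *dominant*: the mandatory package cap gains ≈340k HALYs
over the population's lifetime and saves far more in health-care costs
(AUD −7.1 B discounted) than it costs to implement (AUD ≈223 M), so no ICER
is reported as a ratio. HALY magnitudes depend on the synthetic
epidemiology bundle and are not comparable to estimates built on national
data; orderings (30% cut > 5% cut, mandatory > voluntary) and signs are the
meaningful outputs. By default only cost parameters are sampled, so their
uncertainty intervals are non-degenerate while HALYs are deterministic; set
`sample_effects=True` to propagate effect-size uncertainty too.

The same run is available from the shell:

```bash
ssbcea run --scenario A1 --scenario B1 --synthetic-seed 1 --seed 42 --out out
ssbcea generate --seed 7 --out bundle/   # write a synthetic input bundle
ssbcea validate --bundle bundle/         # check all table invariants
```

Outputs: `results.json` (means, 95% UIs, classification per scenario),
`ce_plane.csv` (per-iteration incremental cost/HALY points) and per-scenario
life-table CSVs.

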