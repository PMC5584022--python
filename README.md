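# dmesrd

An agent-based microsimulation of diabetic end-stage renal disease
(DM-ESRD) in a Saskatchewan-style population, 1980–2025. Individual agents
are followed from diabetes diagnosis through competing-risks ESRD onset or
death, renal replacement therapy (hemodialysis, peritoneal dialysis,
transplantation), the kidney-transplant assessment and waiting-list
pathway, and daily cost accrual — separately for First Nations and
non-First Nations people, the population stratum carrying a
disproportionate diabetes and ESRD burden. It is written for
epidemiologists and health-economics modellers who want to project DM-ESRD
case counts and treatment costs, and to ask "what if" questions (halting
diabetes incidence; universal pre-emptive transplantation) inside a single
reproducible simulator.

## Model

Time advances in 1-day steps on a 1980-01-01 … 2025-12-31 calendar. Four
entry groups populate the model: prevalent diabetes with and without ESRD
at 1980, historic incident diabetes 1980–2005 (8,275 First Nations;
82,306 non-First Nations at full scale), and projected incident diabetes
2006–2025; diagnosis dates are uniform within each incident year.

**Progression.** Pre-ESRD agents face cause-specific daily hazards
*h*<sub>ESRD</sub> and *h*<sub>death</sub> stratified by ethnicity, sex,
5-year age band and time since diagnosis in 3-year stages (capped at
≥24 years). A day's event probability is *p* = 1 − e<sup>−(*h*₁+*h*₂)</sup>,
with the cause drawn proportionally to the cause-specific hazards — exact
for the daily-discretized competing-hazards process.

**Treatment.** Incident ESRD starts dialysis (PD with a year-specific
Bernoulli probability, else HD; bidirectional switching hazards), or —
with a calibrated probability — receives a pre-emptive transplant. Graft
failure follows piecewise-constant hazards recovered from 3-month/1-/3-/5-
year graft-survival fractions by donor type and recipient age group:
on interval (a, b], *h* = ln(S(a)/S(b))/(b−a). Post-transplant time is
staged (≤90 d, 90 d–1 y, >1 y) for mortality and costs. RRT mortality is
a daily hazard stratified by modality/stage, ethnicity, sex, age at
treatment start and time on treatment, with 5-year calendar-period
multipliers on dialysis.

**Transplant pathway.** An age rule refers dialysis patients to assessment
(always ≤65 y, 25% at 66–75 y, never >75 y); assessment duration is
Erlang (number of appointments × mean days per test); eligibility compares
a per-agent Uniform(0,1) health coefficient to a calibrated cutoff.
Eligible patients join a waiting list with random priority: deceased-donor
organs arrive as a Poisson process and go to the highest-priority
candidate, living-donor candidates wait exponential delays, and a
calibrated daily withdrawal hazard applies. Re-assessment after graft
failure within a year of transplant is Triangular(0, 90, 180) days.

**Costs.** HD, PD and the three post-transplant stages accrue annual
2008-CAD costs pro-rated daily; transplant surgery books a one-time cost
(plus a living-donor evaluation surcharge). Discounting is whole-calendar-
year at 3% around base year 2008.

**Scenarios.** `no_new_dm_after_2005` zeroes diabetes incidence from 2006;
`universal_preemptive_tx` transplants every incident ESRD case immediately
and re-transplants failed grafts after exactly 90 days of dialysis. Runs
under one master seed share per-agent random draws (counter-based RNG), so
scenario contrasts are causal.

The true provincial parameter tables come from administrative and registry
sources that are not public; `dmesrd.generate_fixture_bundle(seed, scale)`
produces a complete synthetic bundle with the same schemas and documented
structural properties (see `docs/methods.md`).

## Worked example

```bash
python examples/03_scenarios.py
```

```
scenario 1 (no new diabetes after 2005):
  prevalence peaks in 2021 (inertia: cases keep appearing among pre-2006 diabetics)
  2025 prevalent cases: 54 vs baseline 79

scenario 2 (pre-emptive transplant for every new case), 2016-2025 means:
  prevalent cases: 141 vs baseline 82 (+73%)
  yearly cost:     $5,756,554 vs baseline $6,609,620 (-13%)
```

At 2% population scale, stopping diabetes incidence in 2006 still leaves
DM-ESRD prevalence rising for another 15 years — the system's inertia —
before it falls below the baseline projection. Universal pre-emptive
transplantation raises prevalence by ~73% (transplant recipients survive
much longer than dialysis patients) while *lowering* total yearly cost,
because a maintained graft costs far less per year than hemodialysis.
The other examples cover bundle generation/validation, baseline
projections with multi-realization medians, and calibration recovery.

There is also a thin CLI: `dmesrd fixtures --seed 1 --scale 0.02 --out params/`
writes a bundle, and `dmesrd run --params params/ --scenario s2
--realizations 30 --seed 1 --out runs/` executes a scenario and writes
per-realization event logs, yearly summaries and stacked realizations.

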