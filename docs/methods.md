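# Methods

## Scope and structure

`dmesrd` simulates individual adults (≥20 at diabetes diagnosis) on a
1-day calendar lattice from 1980-01-01 to 2025-12-31. Within each day the
update order is fixed: new entries → pre-ESRD competing-risks progression
→ dialysis mortality and switching → transplant mortality and graft
failure → assessment completions and scheduled re-transplants →
waiting-list events → cost accrual → (on 31 December) the yearly census.
The original system was formulated in continuous time, which has no single
event order; a fixed order is the price of bit-for-bit reproducibility,
and with per-day hazards of order 10⁻⁴–10⁻³ the ordering bias is far below
Monte-Carlo noise.

Dates are integer day offsets from 1980-01-01; leap years are honoured.
Age in completed years is computed as ⌊days/365.2425⌋ rather than by exact
calendar birthdays, so a 5-year hazard-band change can shift by at most
two days relative to the true birthday; all tested day-exact boundaries
(time-on-treatment bands at days 90/365, post-transplant stages, the
90-day scenario-2 re-dialysis spell) use exact day arithmetic.

## Random numbers

Population construction uses one conventional seeded stream per
realization. Every in-run stochastic decision instead uses counter-based
draws: a SplitMix64-style hash of (master seed, decision channel, agent
id, day) mapped to U(0,1). Draws are therefore a pure function of *who*
and *when*, which gives

* determinism — identical (bundle, config, realization) reproduces the
  identical event log;
* process independence — adding or removing one process never perturbs
  another's draws (each decision has its own channel);
* exact common random numbers — two runs under one master seed give the
  same draws to every agent they share, so scenario and parameter
  contrasts diverge only where the change actually bites. This is what
  makes the scenario-1 incidence dominance exact and the calibration
  objective smooth enough to optimize.

Deceased-donor organ arrivals are hashed on the day only, so the arrival
calendar is common across runs under one seed.

## Hazards and discretization

All rates are per-day hazards converted to daily event probabilities by
p = 1 − e⁻ʰ. For two competing causes the total-hazard probability is used
and the cause drawn proportionally — exact for the discretized process.
Daily Bernoulli survival under constant h is geometric with
P(T > k) = e⁻ʰᵏ at integer k, i.e. it matches the continuous exponential
exactly on the day lattice; the test suite verifies this with a
Kolmogorov–Smirnov check on 10,000 simulated lifetimes.

Graft-failure hazards are recovered from survival fractions at 3 months /
1 / 3 / 5 years assuming piecewise-exponential survival within the
published intervals: on (a, b], h = ln(S(a)/S(b))/(b−a), with S(0) = 1 and
the last interval's hazard persisting beyond five years (no post-5-year
information exists). This construction round-trips: simulating the
derived hazards reproduces the input fractions exactly in expectation.

Time-on-treatment clocks for mortality banding reset at each modality
change, and "age at treatment start" is the age at the start of that
episode — one treatment, one clock. Post-transplant stages are ≤90 days,
91–365 days, and beyond; dialysis time bands are [0,90) d, [90,365) d,
1–3 y, 3–5 y, 5 y+. Calendar-period mortality multipliers (5-year
intervals, anchored to 1 in 2005–09 where the source survival analysis
sits) apply to dialysis only; a flag exists to extend them to transplant
recipients but defaults off, since only dialysis rates were described as
period-stratified.

## Transplant pathway conventions

Referral happens at dialysis start (age rule: always ≤65, 25% at 66–75,
never >75). Donor pathway (living vs deceased) is drawn once, at first
assessment, from the year-specific living-donor proportion. Eligibility
compares the agent's fixed Uniform(0,1) health coefficient to the
calibrated cutoff; ineligible patients are flagged and never re-assessed.
Waitlist priority is Uniform(0,1), fixed at listing, ties broken by
earlier listing then id. Living-pathway candidates never compete for
deceased-donor organs. Graft failure within 365 days of transplant
triggers re-assessment (Triangular(0, 90, 180) days) without an
eligibility re-draw — the patient was already deemed eligible; later
failures re-enter the full pathway (the unchanged health coefficient makes
the eligibility outcome deterministic). Re-transplantation without
returning to dialysis exists only inside scenario 2, where it bypasses
assessment, the waiting list and donor supply entirely, 90 days after
failure, with the post-transplant clock restarting at each graft.
Withdrawal from the list is permanent. The triangular minimum of 0 days
for re-assessment is a convention; only the mode (90) and maximum (180)
are constrained.

## Costs

Costed states: HD, PD, transplant stages 1–3, each accruing its annual
2008-CAD cost divided by the days of the calendar year; surgery books a
one-time event cost plus a living-donor evaluation surcharge (charged to
the recipient's ledger, flagged separately in the cost table). Discounting
is whole-calendar-year: every dollar booked in year y carries
(1.03)^(2008−y). The base year 2008 is the costing study's dollar year;
the published discounted/undiscounted cost pairs invert at ≈2008, which is
how the convention was fixed. Both rate and base year are configurable,
and yearly discounted/undiscounted ratios equal the factor exactly by
construction (tested to 2%, the agreement the printed series support).

## The synthetic parameter bundle

The real inputs (provincial administrative data, registry special
requests) are not public, so `generate_fixture_bundle(seed, scale)` emits
a complete synthetic bundle with the same schemas. What is constrained to
match published facts:

* the 1980–2005 incidence schedule sums to 8,275 (First Nations) and
  82,306 (non-First Nations) times `scale`; scaled totals round half-up
  and are apportioned by largest remainder so every table sums exactly;
* First Nations ESRD hazards ≥ non-First Nations in every stratum;
* transplant mortality < dialysis mortality in every stratum, and
  per-patient-year costs order HD > PD > maintained transplant — the
  structure behind the scenario-2 contrast;
* age bands are 5-year 20–24 … 85+ for incidence and 20–74/75+ for
  treatment mortality; the source banding is not printed.

Everything else is a plausibility choice, made once: rising incidence
trends (6%/yr FN, 5%/yr non-FN growth with mild lognormal year noise,
younger and more female onset among First Nations); dialysis mortality
≈12–20%/yr rising with age at start, U-shaped in time on treatment;
transplant mortality 0.45× the dialysis base with stage factors
2.0/1.0/0.8 (early surgical excess, then a sustained survival advantage —
values at which the universal-pre-emptive-transplant scenario reproduces
the documented ≈70% prevalence increase with lower total cost; at much
lower transplant mortality the survival gain is so large that total cost
rises instead); graft survival 95/91/85/78% (deceased) and 97/95/91/86%
(living) worsening with recipient age; PD share of incident dialysis
declining 0.42→0.24 over 1981–2011; living-donor share rising 0.20→0.38
over 1981–1999; 2008-CAD annual costs HD 95k, PD 56k, transplant stages
130k/60k/22k, surgery 60k + 15k living surcharge; calibrated defaults:
withdrawal 5×10⁻⁴/day, eligibility cutoff 0.3, Erlang(4 appointments ×
30 days), pre-emptive probability 0.05 with 0.6 living, period
multipliers declining 1.35→0.84. Prevalent 1980 pools: 20 with ESRD and
24,000 without (×scale); pre-1980 diabetes duration Uniform(0, 15) years
(no-ESRD pool) and Uniform(5, 25) with RRT vintage Uniform(0, 5) years
(ESRD pool).

`scale` multiplies population counts and the population-proportional
deceased-donor arrival rate (0.020/day at full scale); per-person hazards
are scale-free. The fixture emulates the *structure* of the real inputs,
not their levels: passing tests demonstrate correct mechanics, exact
bookkeeping and the documented qualitative contrasts, not agreement with
any historical series — reproducing the provincial validation curves
would require the non-public tables.

## Calibration

The five historically calibrated parameters (waiting-list withdrawal rate,
eligibility cutoff, assessment duration, period-mortality trend,
pre-emptive transplant rate/type) are fit by minimizing a weighted sum of
squared relative errors between mean-over-replication yearly model series
and target series, with common random numbers across evaluations. The
optimizer is a Latin-hypercube design followed by coordinate descent with
halving steps — a standard derivative-free recipe for stochastic
simulators; neither the original objective nor optimizer is documented.
The period trend enters as a single factor t with multiplier t^(ref−i),
anchored to 1 at the 2005–09 reference interval to avoid confounding with
baseline hazards. Because no historical target series exist, the test
surface is parameter recovery on synthetic truth: targets generated by the
model at known parameters (cutoff 0.7, withdrawal 5×10⁻⁴/day) are
recovered within ±0.1 and a factor of 2 respectively under a budget of
200 evaluations. Recovery needs the waiting-list *flow* series (yearly
listings, withdrawals, transplant events) alongside the census series —
census counts alone cannot separate the cutoff from the withdrawal rate.

## Problem sizes and limitations

Tests and examples run at 1–8% population scale over full or truncated
horizons (a full-horizon 1%-scale realization takes a few seconds; the
budget-200 recovery experiment uses a 1980–1995 horizon with ESRD hazards
boosted 15× to concentrate pathway activity). Known limitations: no
under-20 diabetes; no emigration by default (an optional exit hazard
exists, default 0), so incident counts are upper bounds; transplant
selection is age-plus-coefficient only (no comorbidity, blood group or
sensitization); dialysis modality after graft failure is drawn from the
incident-dialysis distribution; costs carry no perspective or inflation
switching; calibration is point estimation, not posterior inference.
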