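"""Daily-step simulation engine, scenario overrides, and run outputs.

Each realization advances one day at a time over the horizon with a fixed
within-day order: new entries, pre-ESRD competing-risks progression, RRT
mortality, graft failure, dialysis switching, assessment completions and
scheduled re-transplants, waiting-list events, cost accrual, and (on 31
December) the yearly census. Stochastic decisions use counter-based draws,
one channel per process, so a given process's draws are unperturbed by
changes elsewhere; the same (bundle, config, realization index) always
reproduces the identical event log.

The two counterfactual scenarios:

* ``no_new_dm_after_2005`` — the incidence schedule is zeroed from 2006;
  agents diagnosed earlier still progress, so prevalence keeps rising for
  years on system inertia alone.
* ``universal_preemptive_tx`` — every ESRD onset receives an immediate
  pre-emptive transplant, and after any graft failure the patient spends
  exactly 90 days on dialysis before re-transplant, bypassing assessment
  and the waiting list (donor supply is not a constraint here).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _rng, codes, population
from ._time import (
    DAYS_PER_YEAR,
    date_to_day,
    day_to_date,
    days_in_year,
    period_index,
    year_of_day,
    year_start_day,
)
from .parameters import ParameterBundle, nearest_year_value
from .progression import compile_competing_risks
from .rrt import MortalityHazardTable, SwitchingHazards, compile_graft_hazards, graft_interval_index
from .transplant import Waitlist, WaitlistRates

__version__ = "0.1.0"

SCENARIOS = ("baseline", "no_new_dm_after_2005", "universal_preemptive_tx")
_SCENARIO_ALIASES = {"s1": "no_new_dm_after_2005", "s2": "universal_preemptive_tx"}

_BIG = np.iinfo(np.int32).max

# counter-based draw channels (see _rng.uniform); one per stochastic decision
CH_PROG_EVENT = 0
CH_PROG_CAUSE = 1
CH_DIAL_MORT = 2
CH_SWITCH = 3
CH_TX_MORT = 4
CH_GRAFT_FAIL = 5
CH_EXIT = 6
CH_LIVING_TX = 7
CH_WITHDRAW = 8
CH_PRIORITY = 9
CH_ASSESS_ERLANG = 10  # spans shape consecutive channels
CH_REASSESS = 40
CH_DONOR_PATHWAY = 41
CH_PREEMPTIVE = 42
CH_PREEMPTIVE_TYPE = 43
CH_MODALITY = 44
CH_REFERRAL_AGE = 45
CH_ORGAN_ARRIVALS = 46


@dataclass
class ScenarioConfig:
    scenario: str = "baseline"
    start_year: int = 1980
    end_year: int = 2025
    n_realizations: int = 30
    master_seed: int = 0
    out_dir: str | None = None
    # optional per-day hazard of leaving the study population (emigration);
    # defaults to 0, matching the original model's stated limitation
    exit_hazard: float = 0.0

    def __post_init__(self):
        self.scenario = _SCENARIO_ALIASES.get(self.scenario, self.scenario)
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}")
        if not (1980 <= self.start_year <= self.end_year <= 2025):
            raise ValueError("horizon must lie within 1980-2025")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")


@dataclass
class ScenarioHooks:
    force_preemptive: bool = False
    retx_gap_days: int | None = None  # days on dialysis before re-transplant


def apply_scenario(config: ScenarioConfig, bundle: ParameterBundle):
    """Scenario-adjusted (bundle, hooks).

    Scenario 1 zeroes the incidence schedule from 2006 onward and touches
    nothing else. Scenario 2 forces the pre-emptive transplant probability
    to one and schedules a re-transplant 90 days after every graft failure.
    """
    if config.scenario == "no_new_dm_after_2005":
        inc = bundle.incidence.copy()
        inc.loc[inc["year"] >= 2006, "count"] = 0
        return dataclasses.replace(bundle, incidence=inc), ScenarioHooks()
    if config.scenario == "universal_preemptive_tx":
        cal = bundle.calibrated.replace(preemptive_transplant_probability=1.0)
        return bundle.with_calibrated(cal), ScenarioHooks(force_preemptive=True, retx_gap_days=90)
    return bundle, ScenarioHooks()


@dataclass
class RunOutput:
    metadata: dict
    events: pd.DataFrame  # agent_id, day, date, from_state, to_state, cause
    yearly: pd.DataFrame  # one row per horizon year
    costs: pd.DataFrame  # year, ethnicity, state, state_days, undiscounted, discounted
    agents: pd.DataFrame  # final per-agent snapshot

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "run_metadata.yaml").write_text(yaml.safe_dump(self.metadata, sort_keys=True))
        self.events.to_csv(out / "events.csv", index=False)
        self.yearly.to_csv(out / "yearly_summary.csv", index=False)
        self.costs.to_csv(out / "costs.csv", index=False)
        self.agents.to_csv(out / "agents.csv", index=False)
        return out


def composite_label(state: int, pathway: int) -> str:
    """The statechart label: dialysis under assessment/listing is shown as such."""
    if state in codes.DIALYSIS_STATES:
        if pathway == codes.PW_ASSESSMENT:
            return "Assessment"
        if pathway == codes.PW_WAITLIST:
            return f"Waitlist({codes.STATE_LABELS[state]})"
    return codes.STATE_LABELS[state]


class _Sim:
    """One realization; struct-of-arrays over agents, daily vectorized steps."""

    def __init__(self, bundle: ParameterBundle, config: ScenarioConfig, realization: int):
        self.bundle, self.hooks = apply_scenario(config, bundle)
        self.config = config
        self.realization = realization

        # population construction uses a conventional stream; every in-run
        # stochastic decision uses counter-based draws (see _rng), a pure
        # function of (seed, channel, agent, day). Draws are therefore
        # identical for any agent two runs share — exact common random
        # numbers across scenarios and parameter settings — and divergence
        # stays local to the agents a change actually touches.
        self.rng_pop = np.random.default_rng(
            np.random.SeedSequence((config.master_seed, realization))
        )
        self.hash_key = _rng.stream_key(config.master_seed, realization)

        b = self.bundle
        self.cr_esrd, self.cr_death = compile_competing_risks(b.competing_risks)
        self.mortality = MortalityHazardTable(
            b.mortality, b.calibrated.period_mortality_multipliers
        )
        self.graft_h = compile_graft_hazards(b.graft_survival)
        sw = SwitchingHazards.from_table(b.switching)
        self.p_switch = np.array(
            [-np.expm1(-sw.h_hd_to_pd), -np.expm1(-sw.h_pd_to_hd)]
        )
        years = np.arange(1980, 2026)
        self.p_pd_by_year = np.array(
            [nearest_year_value(b.modality_probability, int(y), "p_pd_initial") for y in years]
        )
        self.p_living_by_year = np.array(
            [nearest_year_value(b.donor_type, int(y), "p_living") for y in years]
        )
        self.wl_rates = WaitlistRates(
            living=b.transplant_rates["living"],
            deceased=b.transplant_rates["deceased"],
            withdrawal=b.calibrated.withdrawal_rate,
        )
        self.p_living_daily = -np.expm1(-self.wl_rates.living)
        self.p_withdraw_daily = -np.expm1(-self.wl_rates.withdrawal)
        self.annual_cost = np.array(
            [b.costs.annual[k] for k in codes.COSTED_STATE_KEYS]
        )
        self.discount_by_year = (1.0 + b.costs.discount_rate) ** (b.costs.base_year - years)
        self.year0 = 1980

        self._build_agents()
        self._reset_logs()

    # -- setup --------------------------------------------------------------

    def _build_agents(self):
        groups = population.initialize_population(self.bundle, self.rng_pop)
        agents = groups.all_agents()
        n = len(agents)
        self.n = n
        g1 = len(groups.group1)
        self.group_sizes = (
            g1, len(groups.group2), len(groups.group3), len(groups.group4),
        )
        self.eth = np.empty(n, np.int8)
        self.sex = np.empty(n, np.int8)
        self.birth = np.empty(n, np.int32)
        self.dx = np.empty(n, np.int32)
        self.state = np.empty(n, np.int8)
        self.hc = np.empty(n, np.float64)
        self.entry = np.empty(n, np.int32)
        self.episode_start = np.full(n, _BIG, np.int32)
        self.first_rrt = np.full(n, _BIG, np.int32)
        self.tx_day = np.full(n, _BIG, np.int32)
        self.donor = np.full(n, -1, np.int8)
        self.tx_age_group = np.full(n, -1, np.int8)
        self.age_start_band = np.full(n, -1, np.int8)
        self.pathway = np.full(n, codes.PW_NONE, np.int8)
        self.donor_pathway = np.full(n, -1, np.int8)
        self.priority = np.full(n, np.nan)
        self.assess_end = np.full(n, _BIG, np.int32)
        self.skip_elig = np.zeros(n, bool)
        self.retx_day = np.full(n, _BIG, np.int32)
        self.cum_cost = np.zeros(n)
        self.cum_cost_disc = np.zeros(n)

        start_day = year_start_day(self.config.start_year)
        state_code = {lbl: i for i, lbl in enumerate(codes.STATE_LABELS)}
        for i, a in enumerate(agents):
            self.eth[i] = codes.ETH_CODE[a.ethnicity]
            self.sex[i] = codes.SEX_CODE[a.sex]
            self.birth[i] = date_to_day(a.birth_date)
            self.dx[i] = date_to_day(a.dm_diagnosis_date)
            self.state[i] = state_code[a.state]
            self.hc[i] = a.health_coefficient
            self.entry[i] = max(date_to_day(a.state_entry_date), start_day)
            if a.rrt_start_date is not None:
                d = date_to_day(a.rrt_start_date)
                self.episode_start[i] = d
                self.first_rrt[i] = d
                self.age_start_band[i] = codes.mortality_age_band_index(
                    int((d - self.birth[i]) // DAYS_PER_YEAR)
                )
            if a.transplant_date is not None:
                self.tx_day[i] = date_to_day(a.transplant_date)
                self.donor[i] = codes.DONOR_CODE[a.donor_type]
                age = int((self.tx_day[i] - self.birth[i]) // DAYS_PER_YEAR)
                self.tx_age_group[i] = codes.graft_age_group_index(age)
                self.pathway[i] = codes.PW_POSTTX
        # prevalent RRT agents never went through the modelled referral, so
        # treat them as referable on graft failure like anyone else
        self.order = np.argsort(self.entry, kind="stable").astype(np.int64)

    def _reset_logs(self):
        self.ev_id: list[int] = []
        self.ev_day: list[int] = []
        self.ev_from: list[str] = []
        self.ev_to: list[str] = []
        self.ev_cause: list[str] = []
        ny = self.config.end_year - self.config.start_year + 1
        self.incident_esrd = np.zeros(ny, np.int64)
        self.deaths_esrd = np.zeros(ny, np.int64)
        # waiting-list flow counters (per year): listings, withdrawals and
        # transplant events — the identifying signal for calibration
        self.n_listings = np.zeros(ny, np.int64)
        self.n_withdrawals = np.zeros(ny, np.int64)
        self.n_transplants = np.zeros(ny, np.int64)
        # cost accumulators: [year, ethnicity, costed state + transplant_event]
        self.cost_states = list(codes.COSTED_STATE_KEYS) + ["transplant_event"]
        self.cost_und = np.zeros((ny, 2, len(self.cost_states)))
        self.cost_dis = np.zeros((ny, 2, len(self.cost_states)))
        self.state_days = np.zeros((ny, 2, len(self.cost_states)), np.int64)
        self.yearly_rows: list[dict] = []
        self.wl = Waitlist()

    def _log(self, i: int, day: int, frm: str, to: str, cause: str):
        self.ev_id.append(int(i))
        self.ev_day.append(int(day))
        self.ev_from.append(frm)
        self.ev_to.append(to)
        self.ev_cause.append(cause)

    # -- transitions --------------------------------------------------------

    def _die(self, i: int, day: int):
        frm = composite_label(self.state[i], self.pathway[i])
        if self.state[i] != codes.DM:
            self.deaths_esrd[year_of_day(day) - self.config.start_year] += 1
        if i in self.wl.entries:
            self.wl.remove(i)
            self._log(i, day, frm, frm, "delisted_death")
        self.state[i] = codes.DEAD
        self._log(i, day, frm, "Dead", "death")

    def _start_dialysis(self, i: int, day: int, cause: str):
        frm = composite_label(self.state[i], self.pathway[i])
        year_ix = min(max(year_of_day(day) - 1980, 0), 45)
        pd_pick = (
            _rng.uniform1(self.hash_key, CH_MODALITY, i, day) < self.p_pd_by_year[year_ix]
        )
        self.state[i] = codes.PD if pd_pick else codes.HD
        self.episode_start[i] = day
        if self.first_rrt[i] == _BIG:
            self.first_rrt[i] = day
        age = int((day - self.birth[i]) // DAYS_PER_YEAR)
        self.age_start_band[i] = codes.mortality_age_band_index(age)
        self._log(i, day, frm, codes.STATE_LABELS[self.state[i]], cause)

    def _begin_assessment(self, i: int, day: int, is_reassessment: bool):
        year_ix = min(max(year_of_day(day) - 1980, 0), 45)
        if self.donor_pathway[i] < 0:
            self.donor_pathway[i] = (
                codes.LIVING
                if _rng.uniform1(self.hash_key, CH_DONOR_PATHWAY, i, day)
                < self.p_living_by_year[year_ix]
                else codes.DECEASED
            )
        cal = self.bundle.calibrated
        if is_reassessment:
            # re-assessment after early graft failure: triangular, <=180 d
            u = _rng.uniform1(self.hash_key, CH_REASSESS, i, day)
            dur = _rng.triangular1(u, 0.0, 90.0, 180.0)
        else:
            dur = _rng.erlang1(
                self.hash_key, CH_ASSESS_ERLANG, i, day,
                int(cal.assessment_appointments), cal.assessment_mean_days_per_test,
            )
        frm = composite_label(self.state[i], self.pathway[i])
        self.pathway[i] = codes.PW_ASSESSMENT
        self.skip_elig[i] = is_reassessment
        self.assess_end[i] = day + max(1, int(round(dur)))
        self._log(i, day, frm, "Assessment", "assessment_start")

    def _refer(self, i: int, day: int, is_reassessment: bool = False):
        """Referral decision at dialysis start (or after late graft failure).

        The age rule: never above 75, 25% chance at 66-75, always at <=65.
        """
        age = int((day - self.birth[i]) // DAYS_PER_YEAR)
        if age > 75:
            ok = False
        elif age >= 66:
            ok = _rng.uniform1(self.hash_key, CH_REFERRAL_AGE, i, day) < 0.25
        else:
            ok = True
        if ok:
            self._begin_assessment(i, day, is_reassessment)
        else:
            self.pathway[i] = codes.PW_DECLINED

    def _transplant(self, i: int, day: int, donor: int, cause: str):
        frm = composite_label(self.state[i], self.pathway[i])
        self.state[i] = codes.TX
        self.tx_day[i] = day
        self.donor[i] = donor
        self.episode_start[i] = day
        age = int((day - self.birth[i]) // DAYS_PER_YEAR)
        self.age_start_band[i] = codes.mortality_age_band_index(age)
        self.tx_age_group[i] = int(codes.graft_age_group_index(age))
        self.pathway[i] = codes.PW_POSTTX
        self.retx_day[i] = _BIG
        self.n_transplants[year_of_day(day) - self.config.start_year] += 1
        self._log(i, day, frm, "Transplant", cause)
        # one-time event cost (plus living-donor evaluation surcharge)
        c = self.bundle.costs.transplant_event
        if donor == codes.LIVING:
            c += self.bundle.costs.living_donor_surcharge
        y = year_of_day(day) - self.config.start_year
        e = self.eth[i]
        k = self.cost_states.index("transplant_event")
        self.cost_und[y, e, k] += c
        self.cost_dis[y, e, k] += c * self.discount_by_year[year_of_day(day) - 1980]
        self.cum_cost[i] += c
        self.cum_cost_disc[i] += c * self.discount_by_year[year_of_day(day) - 1980]

    def _esrd_onset(self, i: int, day: int):
        self.incident_esrd[year_of_day(day) - self.config.start_year] += 1
        cal = self.bundle.calibrated
        p = 1.0 if self.hooks.force_preemptive else cal.preemptive_transplant_probability
        if _rng.uniform1(self.hash_key, CH_PREEMPTIVE, i, day) < p:
            donor = (
                codes.LIVING
                if _rng.uniform1(self.hash_key, CH_PREEMPTIVE_TYPE, i, day)
                < cal.preemptive_living_fraction
                else codes.DECEASED
            )
            self._transplant(i, day, donor, "preemptive_transplant")
        else:
            self._start_dialysis(i, day, "esrd_onset")
            self._refer(i, day)

    def _graft_failure(self, i: int, day: int):
        early = (day - self.tx_day[i]) <= 365
        self._start_dialysis(i, day, "graft_failure")
        if self.hooks.retx_gap_days is not None:
            self.retx_day[i] = day + self.hooks.retx_gap_days
        elif early:
            # re-assessment within 180 days; eligibility already established
            self._begin_assessment(i, day, is_reassessment=True)
        else:
            self._refer(i, day)

    # -- the daily loop -----------------------------------------------------

    def run(self) -> RunOutput:
        cfg = self.config
        start_day = year_start_day(cfg.start_year)
        end_day = year_start_day(cfg.end_year + 1) - 1
        entry_sorted = self.order
        entry_days = self.entry[entry_sorted]
        ptr = 0
        alive = np.empty(0, np.int64)
        year = cfg.start_year
        diy = days_in_year(year)
        year_end = year_start_day(year + 1) - 1
        disc = self.discount_by_year[year - 1980]
        period_mult = float(
            self.bundle.calibrated.period_mortality_multipliers[int(period_index(year))]
        )
        n_costed = len(self.cost_states)

        for day in range(start_day, end_day + 1):
            # --- entries
            if ptr < len(entry_days) and entry_days[ptr] <= day:
                hi = int(np.searchsorted(entry_days, day, side="right"))
                new = entry_sorted[ptr:hi]
                ptr = hi
                for i in new:
                    self._log(
                        int(i), day, "", composite_label(self.state[i], self.pathway[i]), "entry"
                    )
                alive = np.concatenate([alive, new])

            if alive.size:
                st = self.state[alive]

                # --- pre-ESRD competing risks
                dm = alive[st == codes.DM]
                if dm.size:
                    age = ((day - self.birth[dm]) // DAYS_PER_YEAR).astype(np.int64)
                    band = codes.age_band_index(age)
                    stage = np.minimum(
                        ((day - self.dx[dm]) / DAYS_PER_YEAR / 3.0).astype(np.int64),
                        codes.N_DURATION_STAGES - 1,
                    )
                    h_e = self.cr_esrd[self.eth[dm], self.sex[dm], band, stage]
                    h_d = self.cr_death[self.eth[dm], self.sex[dm], band, stage]
                    tot = h_e + h_d
                    u = _rng.uniform(self.hash_key, 0, dm, day)
                    hit = u < -np.expm1(-tot)
                    if hit.any():
                        idx = np.flatnonzero(hit)
                        u2 = _rng.uniform(self.hash_key, 1, dm[idx], day)
                        with np.errstate(invalid="ignore"):
                            is_esrd = u2 < np.where(tot[idx] > 0, h_e[idx] / tot[idx], 0.0)
                        for j, onset in zip(idx, is_esrd):
                            i = int(dm[j])
                            if onset:
                                self._esrd_onset(i, day)
                            else:
                                self._die(i, day)

                # --- dialysis mortality and switching
                dial = alive[(st == codes.HD) | (st == codes.PD)]
                if dial.size:
                    mod = (self.state[dial] == codes.PD).astype(np.int64)
                    tb = codes.dialysis_time_band_index(day - self.episode_start[dial])
                    h = (
                        self.mortality.dialysis[
                            mod, self.eth[dial], self.sex[dial], self.age_start_band[dial], tb
                        ]
                        * period_mult
                    )
                    dead = _rng.uniform(self.hash_key, 2, dial, day) < -np.expm1(-h)
                    for i in dial[dead]:
                        self._die(int(i), day)
                    surv = dial[~dead]
                    if surv.size:
                        p_sw = self.p_switch[(self.state[surv] == codes.PD).astype(np.int64)]
                        swm = _rng.uniform(self.hash_key, 3, surv, day) < p_sw
                        for i in surv[swm]:
                            i = int(i)
                            frm = composite_label(self.state[i], self.pathway[i])
                            self.state[i] = (
                                codes.PD if self.state[i] == codes.HD else codes.HD
                            )
                            # new treatment episode: clocks and age-at-start reset
                            self.episode_start[i] = day
                            self.age_start_band[i] = codes.mortality_age_band_index(
                                int((day - self.birth[i]) // DAYS_PER_YEAR)
                            )
                            self._log(
                                i, day, frm,
                                composite_label(self.state[i], self.pathway[i]),
                                "modality_switch",
                            )

                # --- transplant mortality and graft failure
                txs = alive[self.state[alive] == codes.TX]
                if txs.size:
                    dst = day - self.tx_day[txs]
                    stg = codes.tx_stage_index(dst)
                    h_m = self.mortality.transplant[
                        self.eth[txs], self.sex[txs], self.age_start_band[txs], stg
                    ]
                    dead = _rng.uniform(self.hash_key, 4, txs, day) < -np.expm1(-h_m)
                    for i in txs[dead]:
                        self._die(int(i), day)
                    surv = txs[~dead]
                    if surv.size:
                        gi = graft_interval_index(day - self.tx_day[surv])
                        h_g = self.graft_h[self.donor[surv], self.tx_age_group[surv], gi]
                        fail = _rng.uniform(self.hash_key, 5, surv, day) < -np.expm1(-h_g)
                        for i in surv[fail]:
                            self._graft_failure(int(i), day)

                # --- scheduled pathway events
                pend = alive[
                    (self.pathway[alive] == codes.PW_ASSESSMENT)
                    & (self.assess_end[alive] <= day)
                    & (self.state[alive] != codes.DEAD)
                ]
                for i in pend:
                    i = int(i)
                    if self.state[i] not in codes.DIALYSIS_STATES:
                        continue  # e.g. transplanted through another route
                    cutoff = self.bundle.calibrated.eligibility_cutoff
                    if self.skip_elig[i] or self.hc[i] >= cutoff:
                        frm = composite_label(self.state[i], self.pathway[i])
                        self.pathway[i] = codes.PW_WAITLIST
                        self.priority[i] = _rng.uniform1(self.hash_key, CH_PRIORITY, i, day)
                        self.wl.add(
                            i,
                            float(self.priority[i]),
                            codes.DONOR_TYPES[self.donor_pathway[i]],
                            day,
                        )
                        self.n_listings[year - cfg.start_year] += 1
                        self._log(
                            i, day, frm, composite_label(self.state[i], self.pathway[i]), "listed"
                        )
                    else:
                        self.pathway[i] = codes.PW_INELIGIBLE
                        self._log(i, day, "Assessment", composite_label(self.state[i], self.pathway[i]), "ineligible")
                    self.assess_end[i] = _BIG

                rtx = alive[
                    (self.retx_day[alive] <= day)
                    & ((self.state[alive] == codes.HD) | (self.state[alive] == codes.PD))
                ]
                for i in rtx:
                    cal = self.bundle.calibrated
                    donor = (
                        codes.LIVING
                        if _rng.uniform1(self.hash_key, CH_PREEMPTIVE_TYPE, int(i), day)
                        < cal.preemptive_living_fraction
                        else codes.DECEASED
                    )
                    self._transplant(int(i), day, donor, "retransplant")

                # --- waiting list: deceased organs arrive as a (counter-
                # based) Poisson process shared by all runs under one seed
                # and go to the highest-priority deceased-pathway member;
                # living-pathway members and withdrawals are per-agent
                # daily hazards
                n_organs = _rng.poisson1(
                    self.hash_key, CH_ORGAN_ARRIVALS, day, self.wl_rates.deceased
                )
                for _ in range(n_organs):
                    top = self.wl.highest_priority("deceased")
                    if top is None:
                        break  # organ goes unused by this population
                    self.wl.remove(top.agent_id)
                    self._transplant(top.agent_id, day, codes.DECEASED, "transplant")
                living = [e.agent_id for e in self.wl.members("living")]
                if living:
                    u = _rng.uniform(self.hash_key, CH_LIVING_TX, np.array(living), day)
                    for i in np.array(living)[u < self.p_living_daily]:
                        self.wl.remove(int(i))
                        self._transplant(int(i), day, codes.LIVING, "transplant")
                listed = list(self.wl.entries.keys())
                if listed:
                    u = _rng.uniform(self.hash_key, CH_WITHDRAW, np.array(listed), day)
                    for i in np.array(listed)[u < self.p_withdraw_daily]:
                        i = int(i)
                        self.wl.remove(i)
                        frm = composite_label(self.state[i], self.pathway[i])
                        self.pathway[i] = codes.PW_WITHDRAWN
                        self.n_withdrawals[year - cfg.start_year] += 1
                        self._log(
                            i, day, frm,
                            composite_label(self.state[i], self.pathway[i]),
                            "withdrawal",
                        )

                # --- optional study exit (emigration), off by default
                if cfg.exit_hazard > 0:
                    live = alive[self.state[alive] < codes.DEAD]
                    exits = live[
                        _rng.uniform(self.hash_key, 6, live, day)
                        < -np.expm1(-cfg.exit_hazard)
                    ]
                    for i in exits:
                        i = int(i)
                        frm = composite_label(self.state[i], self.pathway[i])
                        if i in self.wl.entries:
                            self.wl.remove(i)
                        self.state[i] = codes.EXITED
                        self._log(i, day, frm, "Exited", "study_exit")

                # --- drop the dead, accrue costs for the living
                alive = alive[self.state[alive] < codes.DEAD]
                if alive.size:
                    st = self.state[alive]
                    costed = alive[st != codes.DM]
                    if costed.size:
                        sc = self.state[costed].astype(np.int64) - 1  # HD->0, PD->1, TX->2
                        is_tx = sc == 2
                        if is_tx.any():
                            sc = sc + np.where(
                                is_tx, codes.tx_stage_index(day - self.tx_day[costed]), 0
                            )
                        daily = self.annual_cost[sc] / diy
                        self.cum_cost[costed] += daily
                        self.cum_cost_disc[costed] += daily * disc
                        flat = (self.eth[costed].astype(np.int64)) * n_costed + sc
                        sums = np.bincount(flat, weights=daily, minlength=2 * n_costed)
                        cnts = np.bincount(flat, minlength=2 * n_costed)
                        y = year - cfg.start_year
                        self.cost_und[y] += sums.reshape(2, n_costed)
                        self.cost_dis[y] += (sums * disc).reshape(2, n_costed)
                        self.state_days[y] += cnts.reshape(2, n_costed).astype(np.int64)

            # --- yearly census on 31 December
            if day == year_end:
                self._census(year, alive)
                year += 1
                if year <= cfg.end_year:
                    diy = days_in_year(year)
                    year_end = year_start_day(year + 1) - 1
                    disc = self.discount_by_year[year - 1980]
                    period_mult = float(
                        self.bundle.calibrated.period_mortality_multipliers[
                            int(period_index(year))
                        ]
                    )

        return self._output(alive)

    def _census(self, year: int, alive: np.ndarray):
        st = self.state[alive]
        esrd = alive[(st == codes.HD) | (st == codes.PD) | (st == codes.TX)]
        y = year - self.config.start_year
        row = {
            "year": year,
            "incident_esrd": int(self.incident_esrd[y]),
            "deaths_esrd": int(self.deaths_esrd[y]),
            "prev_total": int(esrd.size),
            "prev_FN": int((self.eth[esrd] == 0).sum()),
            "prev_nonFN": int((self.eth[esrd] == 1).sum()),
            "prev_hd": int((self.state[alive] == codes.HD).sum()),
            "prev_pd": int((self.state[alive] == codes.PD).sum()),
            "prev_tx": int((self.state[alive] == codes.TX).sum()),
            "waitlist_total": self.wl.census()["total"],
            "waitlist_living": self.wl.census()["living"],
            "waitlist_deceased": self.wl.census()["deceased"],
            "listings": int(self.n_listings[y]),
            "withdrawals": int(self.n_withdrawals[y]),
            "transplants": int(self.n_transplants[y]),
            "cost_undiscounted": float(self.cost_und[y].sum()),
            "cost_discounted": float(self.cost_dis[y].sum()),
            "cost_FN_undiscounted": float(self.cost_und[y, 0].sum()),
            "cost_nonFN_undiscounted": float(self.cost_und[y, 1].sum()),
        }
        self.yearly_rows.append(row)

    def _output(self, alive: np.ndarray) -> RunOutput:
        cfg = self.config
        events = pd.DataFrame(
            {
                "agent_id": np.array(self.ev_id, np.int64),
                "day": np.array(self.ev_day, np.int64),
                "date": [day_to_date(d) for d in self.ev_day],
                "from_state": self.ev_from,
                "to_state": self.ev_to,
                "cause": self.ev_cause,
            }
        )
        yearly = pd.DataFrame(self.yearly_rows)
        ny = cfg.end_year - cfg.start_year + 1
        rows = []
        for y in range(ny):
            for e in range(2):
                for k, sname in enumerate(self.cost_states):
                    rows.append(
                        (
                            cfg.start_year + y,
                            codes.ETHNICITIES[e],
                            sname,
                            int(self.state_days[y, e, k]),
                            float(self.cost_und[y, e, k]),
                            float(self.cost_dis[y, e, k]),
                        )
                    )
        costs = pd.DataFrame(
            rows,
            columns=["year", "ethnicity", "state", "state_days", "undiscounted", "discounted"],
        )
        agents = pd.DataFrame(
            {
                "agent_id": np.arange(self.n),
                "ethnicity": np.array(codes.ETHNICITIES)[self.eth.astype(int)],
                "sex": np.array(codes.SEXES)[self.sex.astype(int)],
                "birth_day": self.birth,
                "dm_diagnosis_day": self.dx,
                "state": np.array(codes.STATE_LABELS)[self.state.astype(int)],
                "pathway": np.array(codes.PATHWAY_LABELS)[self.pathway.astype(int)],
                "health_coefficient": self.hc,
                "cumulative_cost": self.cum_cost,
                "cumulative_discounted_cost": self.cum_cost_disc,
            }
        )
        n_dead = int((self.state == codes.DEAD).sum())
        n_exited = int((self.state == codes.EXITED).sum())
        metadata = {
            "model_version": __version__,
            "scenario": cfg.scenario,
            "start_year": cfg.start_year,
            "end_year": cfg.end_year,
            "master_seed": int(cfg.master_seed),
            "realization": int(self.realization),
            "schema_version": int(self.bundle.schema_version),
            "group_sizes": list(map(int, self.group_sizes)),
            "agents_created": int(self.n),
            "agents_alive_at_end": int(alive.size),
            "agents_dead": n_dead,
            "agents_exited": n_exited,
        }
        return RunOutput(metadata, events, yearly, costs, agents)


def run_realization(
    bundle: ParameterBundle, config: ScenarioConfig, realization: int = 0
) -> RunOutput:
    """Run one seeded realization of the configured scenario."""
    return _Sim(bundle, config, realization).run()


def run_scenario(bundle: ParameterBundle, config: ScenarioConfig) -> list[RunOutput]:
    """All realizations of a scenario (the study convention is 30)."""
    return [run_realization(bundle, config, r) for r in range(config.n_realizations)]


# ---------------------------------------------------------------------------
# multi-realization summaries


def summarize_realizations(outputs: list[RunOutput]):
    """Stacked yearly table plus per-year medians and quartiles.

    Returns ``(stacked, summary)``: ``stacked`` is long-format (year,
    variable, realization, value) suitable for 2-D histogram plotting;
    ``summary`` holds per-(year, variable) median/q25/q75, the convention
    used to report prevalent case counts.
    """
    if not outputs:
        raise ValueError("need at least one realization")
    frames = []
    for r, out in enumerate(outputs):
        long = out.yearly.melt(id_vars="year", var_name="variable", value_name="value")
        long["realization"] = r
        frames.append(long)
    stacked = pd.concat(frames, ignore_index=True)[
        ["year", "variable", "realization", "value"]
    ]
    summary = (
        stacked.groupby(["year", "variable"])["value"]
        .agg(median="median", q25=lambda s: s.quantile(0.25), q75=lambda s: s.quantile(0.75))
        .reset_index()
    )
    return stacked, summary


def export_histogram_data(
    stacked: pd.DataFrame, variable: str, out_path: str | Path, bins: int = 30
):
    """Data-only 2-D histogram export: stacked values + binning metadata."""
    sub = stacked[stacked["variable"] == variable]
    out_path = Path(out_path)
    sub.to_csv(out_path, index=False)
    lo, hi = float(sub["value"].min()), float(sub["value"].max())
    meta = {
        "variable": variable,
        "value_bins": bins,
        "value_range": [lo, hi],
        "years": [int(sub["year"].min()), int(sub["year"].max())],
        "realizations": int(sub["realization"].nunique()),
    }
    out_path.with_suffix(".meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return meta
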