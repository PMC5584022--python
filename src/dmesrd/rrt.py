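"""Renal replacement therapy dynamics.

Covers initial-modality selection (Bernoulli PD-vs-HD by calendar year),
pre-emptive transplantation at ESRD onset, bidirectional HD<->PD switching,
graft failure via piecewise-constant hazards recovered from published-style
survival fractions, the three post-transplant stages (<=90 d, 90 d-1 y,
>1 y), and covariate-stratified daily mortality on treatment.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np

from . import codes
from ._time import period_index, N_PERIODS
from .parameters import nearest_year_value


# ---------------------------------------------------------------------------
# modality selection

def select_initial_modality(year: int, table, rng: np.random.Generator) -> str:
    """'PD' with the year's p_pd_initial (nearest covered year), else 'HD'.

    Used both at first dialysis and on return to dialysis after graft
    failure (the model draws from the same distribution in both cases).
    """
    p = nearest_year_value(table, year, "p_pd_initial")
    return "PD" if rng.random() < p else "HD"


def maybe_preemptive_transplant(agent, params, rng: np.random.Generator) -> str:
    """At ESRD onset, before dialysis: 'none', 'living' or 'deceased'.

    With the calibrated pre-emptive probability the agent bypasses dialysis
    entirely; donor type follows the calibrated living fraction.
    """
    if rng.random() >= params.preemptive_transplant_probability:
        return "none"
    return "living" if rng.random() < params.preemptive_living_fraction else "deceased"


# ---------------------------------------------------------------------------
# graft failure

def compile_graft_hazards(table) -> np.ndarray:
    """Per-day hazards [donor, age group, interval] from survival fractions.

    Piecewise-exponential on (0,90d], (90d,1y], (1y,3y], (3y,5y]:
    ``h = ln(S(a)/S(b)) / (b - a)`` with S(0)=1; beyond five years the last
    interval's hazard persists.
    """
    h = np.full((2, codes.N_GRAFT_AGE_GROUPS, 4), np.nan)
    widths = np.diff(codes.GRAFT_INTERVAL_EDGES)  # 90, 275, 730, 730 days
    for _, row in table.iterrows():
        d = codes.DONOR_CODE[row["donor_type"]]
        g = codes.GRAFT_AGE_GROUPS.index(row["age_group"])
        s = np.array([1.0] + [float(row[c]) for c in codes.GRAFT_SURVIVAL_COLUMNS])
        if np.any(np.diff(s) > 0) or s[-1] <= 0:
            raise ValueError(
                f"graft survival not monotone in (0, 1] for stratum "
                f"(donor_type={row['donor_type']}, age_group={row['age_group']})"
            )
        h[d, g] = np.log(s[:-1] / s[1:]) / widths
    if np.isnan(h).any():
        raise ValueError("graft-survival table does not cover every stratum")
    return h


def graft_failure_hazard(donor_type: str, age_group: str, days_since_transplant: float, table) -> float:
    """Per-day graft-failure hazard at a given time post transplant."""
    h = compile_graft_hazards(table)
    d = codes.DONOR_CODE[donor_type]
    g = codes.GRAFT_AGE_GROUPS.index(age_group)
    i = min(
        int(np.searchsorted(codes.GRAFT_INTERVAL_EDGES[1:], days_since_transplant, side="left")),
        3,
    )
    return float(h[d, g, i])


def graft_interval_index(days_since_transplant) -> np.ndarray:
    """Interval containing a post-transplant day: (0,90], (90,365], (365,1095], beyond."""
    d = np.asarray(days_since_transplant)
    return np.minimum(np.searchsorted(codes.GRAFT_INTERVAL_EDGES[1:], d, side="left"), 3)


# ---------------------------------------------------------------------------
# mortality on treatment

class MortalityHazardTable:
    """Stratified per-day RRT mortality with calendar-period multipliers.

    Dialysis strata are keyed by (modality, ethnicity, sex, age-at-start
    band, time-on-treatment band) and scaled by a 5-year calendar-period
    multiplier (survival on dialysis improved over the simulated decades);
    transplant strata are keyed by post-transplant stage instead of a time
    band and, by default, take no period multiplier.
    """

    def __init__(self, table, period_multipliers=None, apply_period_to_transplant: bool = False):
        self.table = table
        self.period_multipliers = (
            np.ones(N_PERIODS) if period_multipliers is None else np.asarray(period_multipliers, float)
        )
        self.apply_period_to_transplant = apply_period_to_transplant
        self.dialysis, self.transplant = self._compile(table)

    @staticmethod
    def _compile(table):
        band_ix = {b: i for i, b in enumerate(codes.MORTALITY_AGE_BANDS)}
        dial = np.full((2, 2, 2, codes.N_MORT_AGE_BANDS, len(codes.DIALYSIS_TIME_BANDS)), np.nan)
        tx = np.full((2, 2, codes.N_MORT_AGE_BANDS, len(codes.TX_STAGES)), np.nan)
        for _, row in table.iterrows():
            e = codes.ETH_CODE[row["ethnicity"]]
            s = codes.SEX_CODE[row["sex"]]
            b = band_ix[row["age_start_band"]]
            if row["modality"] == "TX":
                tx[e, s, b, codes.TX_STAGES.index(row["time_band"])] = row["hazard_per_day"]
            else:
                m = 0 if row["modality"] == "HD" else 1
                dial[m, e, s, b, codes.DIALYSIS_TIME_BANDS.index(row["time_band"])] = row[
                    "hazard_per_day"
                ]
        if np.isnan(dial).any() or np.isnan(tx).any():
            raise ValueError("mortality table does not cover every stratum")
        return dial, tx


def mortality_hazard(agent, table: MortalityHazardTable, day: _dt.date) -> float:
    """Per-day death hazard for an agent on RRT, looked up fresh each day.

    Stratum: current modality (or post-transplant stage), ethnicity, sex,
    age at the start of the current treatment episode, and time on that
    treatment; the calendar-period multiplier applies to dialysis states.
    """
    if agent.state not in ("HD", "PD", "Transplant"):
        raise ValueError(f"agent {agent.id} not on RRT (state {agent.state})")
    e = codes.ETH_CODE[agent.ethnicity]
    s = codes.SEX_CODE[agent.sex]
    start = agent.rrt_start_date
    b = int(codes.mortality_age_band_index(agent.age_on(start)))
    if agent.state == "Transplant":
        dst = (day - agent.transplant_date).days
        h = float(table.transplant[e, s, b, int(codes.tx_stage_index(dst))])
        if table.apply_period_to_transplant:
            h *= float(table.period_multipliers[int(period_index(day.year))])
        return h
    m = 0 if agent.state == "HD" else 1
    tb = int(codes.dialysis_time_band_index((day - start).days))
    h = float(table.dialysis[m, e, s, b, tb])
    return h * float(table.period_multipliers[int(period_index(day.year))])


# ---------------------------------------------------------------------------
# dialysis switching

@dataclass
class SwitchingHazards:
    h_hd_to_pd: float
    h_pd_to_hd: float

    @classmethod
    def from_table(cls, table) -> "SwitchingHazards":
        kv = dict(zip(table["direction"], table["hazard_per_day"]))
        return cls(h_hd_to_pd=float(kv["hd_to_pd"]), h_pd_to_hd=float(kv["pd_to_hd"]))


def dialysis_switch_step(agent, hazards: SwitchingHazards, rng: np.random.Generator) -> str:
    """Daily Bernoulli modality switch: 'switch' with p = 1 - exp(-h)."""
    if agent.state not in ("HD", "PD"):
        raise ValueError(f"agent {agent.id} not on dialysis (state {agent.state})")
    h = hazards.h_hd_to_pd if agent.state == "HD" else hazards.h_pd_to_hd
    return "switch" if rng.random() < -np.expm1(-h) else "stay"
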