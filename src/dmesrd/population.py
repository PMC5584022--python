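"""Model population: the agent record and the four entry groups.

Agents are adults (>=20 at diabetes diagnosis) in Saskatchewan, 1980-2025:

* group 1 — prevalent diabetes *with* ESRD at the start of 1980, placed
  directly into renal replacement modalities per the initial-modality split;
* group 2 — prevalent diabetes without ESRD at 1980;
* group 3 — incident diabetes 1980-2005 from the historic-style schedule;
* group 4 — projected incident diabetes 2006-2025 from the same schedule.

Incident diagnosis dates are uniform within the incident year; birth dates
are uniform within the age band at diagnosis.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from . import codes
from ._time import date_to_day, day_to_date, days_in_year, year_start_day, DAYS_PER_YEAR
from .parameters import ParameterBundle, nearest_year_value


@dataclass
class Agent:
    """One simulated person; dates are calendar dates, costs cumulative."""

    id: int
    ethnicity: str  # FN | nonFN
    sex: str  # M | F
    birth_date: _dt.date
    dm_diagnosis_date: _dt.date
    health_coefficient: float  # Uniform(0,1), fixed at creation
    state: str = "DM_no_ESRD"
    state_entry_date: _dt.date | None = None
    rrt_start_date: _dt.date | None = None  # start of the current RRT episode
    first_rrt_date: _dt.date | None = None
    transplant_date: _dt.date | None = None
    donor_type: str | None = None
    waitlist_priority: float | None = None
    cumulative_cost: float = 0.0
    cumulative_discounted_cost: float = 0.0

    def __post_init__(self):
        if self.state_entry_date is None:
            self.state_entry_date = self.dm_diagnosis_date

    def age_on(self, day: _dt.date) -> int:
        """Completed age in years (mean-year convention, see docs)."""
        return int((day - self.birth_date).days // DAYS_PER_YEAR)


@dataclass
class PopulationGroups:
    group1: list[Agent] = field(default_factory=list)  # prevalent DM+ESRD at 1980
    group2: list[Agent] = field(default_factory=list)  # prevalent DM, no ESRD, at 1980
    group3: list[Agent] = field(default_factory=list)  # incident DM 1980-2005
    group4: list[Agent] = field(default_factory=list)  # projected incident DM 2006-2025

    def all_agents(self) -> list[Agent]:
        return self.group1 + self.group2 + self.group3 + self.group4


def band_age_bounds(band: str) -> tuple[float, float]:
    """[lo, hi) age in years for an incidence age band; '85+' spans 85-95."""
    if band.endswith("+"):
        lo = float(band[:-1])
        return lo, lo + 10.0
    lo, hi = band.split("-")
    return float(lo), float(hi) + 1.0


def sample_entry_days(n: int, year: int, rng: np.random.Generator) -> np.ndarray:
    """Epoch-day diagnosis dates uniform over the 365/366 days of ``year``."""
    return year_start_day(year) + rng.integers(0, days_in_year(year), size=n)


def sample_birth_days(
    entry_days: np.ndarray, band: str, rng: np.random.Generator
) -> np.ndarray:
    lo, hi = band_age_bounds(band)
    age_days = rng.uniform(lo * DAYS_PER_YEAR, hi * DAYS_PER_YEAR, size=len(entry_days))
    return np.asarray(entry_days) - np.round(age_days).astype(np.int64)


def schedule_incident_entries(
    schedule, year: int, rng: np.random.Generator, start_id: int = 0
) -> list[tuple[Agent, _dt.date]]:
    """Incident diabetes agents for one calendar year of the schedule.

    Zero-count strata yield no agents. Returns (agent, entry_date) pairs;
    the agent's diagnosis date equals its entry date.
    """
    sub = schedule[schedule["year"] == year]
    out: list[tuple[Agent, _dt.date]] = []
    next_id = start_id
    for _, row in sub.iterrows():
        n = int(row["count"])
        if n == 0:
            continue
        entry = sample_entry_days(n, year, rng)
        birth = sample_birth_days(entry, row["age_band"], rng)
        coeff = rng.random(n)
        for j in range(n):
            d = day_to_date(int(entry[j]))
            out.append(
                (
                    Agent(
                        id=next_id,
                        ethnicity=row["ethnicity"],
                        sex=row["sex"],
                        birth_date=day_to_date(int(birth[j])),
                        dm_diagnosis_date=d,
                        health_coefficient=float(coeff[j]),
                    ),
                    d,
                )
            )
            next_id += 1
    return out


def _prevalent_agents(
    pools, group: str, rng: np.random.Generator, start_id: int
) -> list[Agent]:
    """Agents alive on 1980-01-01 with diabetes onset before the horizon.

    Pre-1980 diabetes duration defaults to Uniform(0, 15) years for the
    no-ESRD pool and Uniform(5, 25) for the with-ESRD pool (who have had
    time to progress); age at diagnosis Uniform(30, 70) / (35, 60).
    """
    day0 = 0  # 1980-01-01
    sub = pools[pools["group"] == group]
    agents: list[Agent] = []
    next_id = start_id
    dur_lo, dur_hi, age_lo, age_hi = (
        (5.0, 25.0, 35.0, 60.0) if group == "dm_esrd_1980" else (0.0, 15.0, 30.0, 70.0)
    )
    for _, row in sub.iterrows():
        n = int(row["count"])
        if n == 0:
            continue
        dur = rng.uniform(dur_lo, dur_hi, n)
        dx_age = rng.uniform(age_lo, age_hi, n)
        coeff = rng.random(n)
        for j in range(n):
            dx_day = day0 - int(round(dur[j] * DAYS_PER_YEAR))
            birth_day = dx_day - int(round(dx_age[j] * DAYS_PER_YEAR))
            agents.append(
                Agent(
                    id=next_id,
                    ethnicity=row["ethnicity"],
                    sex=row["sex"],
                    birth_date=day_to_date(birth_day),
                    dm_diagnosis_date=day_to_date(dx_day),
                    health_coefficient=float(coeff[j]),
                    state_entry_date=day_to_date(day0),
                )
            )
            next_id += 1
    return agents


def initialize_population(
    bundle: ParameterBundle, rng: np.random.Generator
) -> PopulationGroups:
    """Instantiate all four groups from the bundle's schedule and pools.

    Group-1 agents are distributed across HD/PD/Transplant per the bundle's
    initial-modality split, with an RRT vintage uniform in the five years
    before 1980; transplant recipients get a donor type from the earliest
    covered donor-type year.
    """
    if bundle.incidence.empty:
        raise ValueError("empty incidence schedule")

    groups = PopulationGroups()
    next_id = 0

    groups.group1 = _prevalent_agents(bundle.prevalent_pools, "dm_esrd_1980", rng, next_id)
    next_id += len(groups.group1)
    modalities = ("HD", "PD", "TX")
    probs = np.array([bundle.initial_modality[m] for m in modalities])
    p_living_1980 = nearest_year_value(bundle.donor_type, 1980, "p_living")
    for a in groups.group1:
        pick = modalities[rng.choice(3, p=probs)]
        vintage = int(rng.integers(0, int(5 * 365.25)))
        start = day_to_date(-vintage)
        a.rrt_start_date = a.first_rrt_date = start
        a.state_entry_date = start
        if pick == "TX":
            a.state = "Transplant"
            a.transplant_date = start
            a.donor_type = "living" if rng.random() < p_living_1980 else "deceased"
        else:
            a.state = pick

    groups.group2 = _prevalent_agents(bundle.prevalent_pools, "dm_no_esrd_1980", rng, next_id)
    next_id += len(groups.group2)

    for year in sorted(bundle.incidence["year"].unique()):
        pairs = schedule_incident_entries(bundle.incidence, int(year), rng, start_id=next_id)
        agents = [a for a, _ in pairs]
        next_id += len(agents)
        (groups.group3 if year <= 2005 else groups.group4).extend(agents)
    return groups
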