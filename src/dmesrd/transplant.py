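"""Transplant assessment, eligibility, and the waiting list.

The pathway: an age-based referral decision (always assessed at <=65, 25%
chance at 66-75, never above 75), donor-type routing from year-specific
living-donor proportions, an Erlang-distributed assessment duration
(triangular, capped at 180 days with mode 90, for re-assessment after early
graft failure), an eligibility test of the agent's uniform "health
coefficient" against a calibrated cutoff, and a waiting list with random
priority. Deceased-donor organs arrive as a Poisson process and go to the
highest-priority deceased-pathway member; living-donor candidates wait an
exponential operating-room delay; withdrawal is a per-day hazard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def assessment_decision(age_years: float, rng: np.random.Generator) -> bool:
    """Age-based referral rule for transplant assessment."""
    if age_years > 75:
        return False
    if age_years >= 66:
        return rng.random() < 0.25
    return True


def sample_assessment_duration(params, is_reassessment: bool, rng: np.random.Generator) -> float:
    """Assessment duration in days.

    First assessment ~ Erlang(shape = number of appointments, mean = shape x
    mean days per test). Re-assessment after graft failure within a year of
    transplant ~ Triangular(0, mode 90, max 180) days.
    """
    if is_reassessment:
        return float(rng.triangular(0.0, 90.0, 180.0))
    k = int(params.assessment_appointments)
    return float(rng.gamma(shape=k, scale=params.assessment_mean_days_per_test))


def eligibility(agent, cutoff: float) -> bool:
    """Eligible iff the agent's health coefficient reaches the cutoff.

    Accepts an Agent or a bare coefficient. Ineligible patients remain
    permanently on dialysis (never re-assessed outside the early-graft-
    failure rule).
    """
    coeff = getattr(agent, "health_coefficient", agent)
    return float(coeff) >= cutoff


@dataclass(frozen=True)
class WaitlistEntry:
    agent_id: int
    priority: float  # Uniform(0,1), immutable after listing
    pathway: str  # living | deceased
    listing_day: int


@dataclass
class WaitlistRates:
    living: float  # per-agent per-day transplant hazard (living pathway)
    deceased: float  # Poisson arrival rate of deceased-donor organs, per day
    withdrawal: float  # per-agent per-day withdrawal hazard


@dataclass
class Waitlist:
    """Both donor-pathway queues; an agent appears at most once."""

    entries: dict[int, WaitlistEntry] = field(default_factory=dict)

    def add(self, agent_id: int, priority: float, pathway: str, listing_day: int) -> None:
        if agent_id in self.entries:
            raise ValueError(f"agent {agent_id} already listed")
        self.entries[agent_id] = WaitlistEntry(agent_id, priority, pathway, listing_day)

    def remove(self, agent_id: int) -> WaitlistEntry:
        return self.entries.pop(agent_id)

    def members(self, pathway: str | None = None) -> list[WaitlistEntry]:
        es = self.entries.values()
        return [e for e in es if pathway is None or e.pathway == pathway]

    def highest_priority(self, pathway: str) -> WaitlistEntry | None:
        """Top-priority member; ties broken by earlier listing, then id."""
        best = None
        for e in self.members(pathway):
            if best is None or (-e.priority, e.listing_day, e.agent_id) < (
                -best.priority, best.listing_day, best.agent_id,
            ):
                best = e
        return best

    def census(self) -> dict[str, int]:
        return {
            "living": len(self.members("living")),
            "deceased": len(self.members("deceased")),
            "total": len(self.entries),
        }

    def __len__(self) -> int:
        return len(self.entries)


def waitlist_step(
    wl: Waitlist, rates: WaitlistRates, day: int, rng: np.random.Generator
) -> list[tuple]:
    """One day of waiting-list events.

    Returns event tuples: ``('transplant', agent_id, donor_type)`` and
    ``('withdrawal', agent_id)``. Deceased-donor arrivals that find no
    deceased-pathway member are discarded. Transplants are resolved before
    withdrawals, so an agent cannot do both on one day.
    """
    events: list[tuple] = []

    n_organs = rng.poisson(rates.deceased)
    for _ in range(int(n_organs)):
        top = wl.highest_priority("deceased")
        if top is None:
            continue  # organ goes unused by this population
        wl.remove(top.agent_id)
        events.append(("transplant", top.agent_id, "deceased"))

    p_living = -np.expm1(-rates.living)
    for e in list(wl.members("living")):
        if rng.random() < p_living:
            wl.remove(e.agent_id)
            events.append(("transplant", e.agent_id, "living"))

    p_withdraw = -np.expm1(-rates.withdrawal)
    for e in list(wl.entries.values()):
        if rng.random() < p_withdraw:
            wl.remove(e.agent_id)
            events.append(("withdrawal", e.agent_id))
    return events
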