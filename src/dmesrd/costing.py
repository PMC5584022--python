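"""Treatment-cost accrual and discounting.

Costed states are the two dialysis modalities and the three post-transplant
stages; each accrues its annual 2008-CAD cost evenly over the days of the
calendar year. Transplant surgery books a one-time event cost (plus a
living-donor evaluation surcharge) on the day it happens. Discounting is
whole-calendar-year at the schedule's rate around its base year: every
dollar booked in year ``y`` carries factor ``(1+r)^(base_year - y)``, so
costs before the base year compound up and later costs discount down.
"""

from __future__ import annotations

import datetime as _dt

import pandas as pd

from . import codes
from ._time import days_in_year
from .parameters import CostSchedule


def state_cost_key(agent, day: _dt.date) -> str | None:
    """Costed-state key for an agent on a day, or None in uncosted states."""
    if agent.state in ("HD", "PD"):
        return agent.state
    if agent.state == "Transplant":
        dst = (day - agent.transplant_date).days
        return f"TX_stage{int(codes.tx_stage_index(dst)) + 1}"
    return None


def accrue_daily_cost(agent, schedule: CostSchedule, day: _dt.date) -> float:
    """Undiscounted cost accrued by one agent on one day.

    Returns annual cost / days-in-year for the agent's costed state (zero in
    uncosted states such as pre-ESRD diabetes), plus the one-time transplant
    event cost — with the living-donor surcharge when applicable — on the
    day of transplant itself.
    """
    key = state_cost_key(agent, day)
    total = 0.0
    if key is not None:
        total += schedule.annual[key] / days_in_year(day.year)
    if agent.state == "Transplant" and agent.transplant_date == day:
        total += schedule.transplant_event
        if agent.donor_type == "living":
            total += schedule.living_donor_surcharge
    return total


def discount(amount: float, day: _dt.date | int, schedule: CostSchedule) -> float:
    """Present value at the schedule's base year, whole-year convention."""
    year = day if isinstance(day, int) else day.year
    return amount * (1.0 + schedule.discount_rate) ** (schedule.base_year - year)


def aggregate_costs(ledgers: pd.DataFrame, by=("year",)) -> pd.DataFrame:
    """Grouped sums of a per-(year, ethnicity, state) cost ledger.

    ``ledgers`` is the engine's cost table with columns year, ethnicity,
    state, state_days, undiscounted, discounted. Grouping keys partition the
    rows, so group totals always add up to the ungrouped total exactly.
    """
    cols = ["state_days", "undiscounted", "discounted"]
    out = ledgers.groupby(list(by), as_index=False)[cols].sum()
    return out.sort_values(list(by)).reset_index(drop=True)
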