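"""Competing-risks progression from diabetes diagnosis to ESRD or death.

Hazards of ESRD onset and of death without ESRD are stratified by ethnicity,
sex, 5-year age band and time-since-diagnosis in 3-year duration stages up
to a terminal ">=24 years" stage. The daily update converts the total hazard
to an event probability via ``p = 1 - exp(-h)`` and, given an event, picks
the cause proportionally to the cause-specific hazards — exact for the
daily-discretized competing-hazards process.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

from . import codes
from ._time import DAYS_PER_YEAR

NO_EVENT, ESRD_ONSET, DEATH = "no_event", "esrd_onset", "death"


def duration_stage(dm_diagnosis_date, today) -> int:
    """3-year duration-stage index: floor(years/3), capped at stage 8 (>=24y)."""
    if isinstance(dm_diagnosis_date, _dt.date):
        elapsed_days = (today - dm_diagnosis_date).days
    else:
        elapsed_days = today - dm_diagnosis_date
    if elapsed_days < 0:
        raise ValueError("today precedes the diabetes diagnosis date")
    years = elapsed_days / DAYS_PER_YEAR
    return min(int(years // 3), codes.N_DURATION_STAGES - 1)


def compile_competing_risks(table) -> tuple[np.ndarray, np.ndarray]:
    """Dense (ethnicity, sex, age band, duration stage) hazard arrays."""
    shape = (2, 2, codes.N_AGE_BANDS, codes.N_DURATION_STAGES)
    h_esrd = np.full(shape, np.nan)
    h_death = np.full(shape, np.nan)
    band_ix = {b: i for i, b in enumerate(codes.INCIDENCE_AGE_BANDS)}
    stage_ix = {s: i for i, s in enumerate(codes.DURATION_STAGE_LABELS)}
    e = table["ethnicity"].map(codes.ETH_CODE).to_numpy()
    s = table["sex"].map(codes.SEX_CODE).to_numpy()
    b = table["age_band"].map(band_ix).to_numpy()
    d = table["duration_stage"].map(stage_ix).to_numpy()
    h_esrd[e, s, b, d] = table["h_esrd"].to_numpy(float)
    h_death[e, s, b, d] = table["h_death"].to_numpy(float)
    if np.isnan(h_esrd).any() or np.isnan(h_death).any():
        raise ValueError("competing-risks table does not cover every stratum")
    return h_esrd, h_death


def lookup_hazards(table, agent, day: _dt.date) -> tuple[float, float]:
    """(h_esrd, h_death) per day for an agent's current stratum.

    ``table`` is either the stratified DataFrame or the dense array pair
    from :func:`compile_competing_risks` (much faster for repeated calls).
    """
    stage = duration_stage(agent.dm_diagnosis_date, day)
    if isinstance(table, tuple):
        h_esrd, h_death = table
        e = codes.ETH_CODE[agent.ethnicity]
        s = codes.SEX_CODE[agent.sex]
        b = int(codes.age_band_index(agent.age_on(day)))
        return float(h_esrd[e, s, b, stage]), float(h_death[e, s, b, stage])
    band = codes.INCIDENCE_AGE_BANDS[int(codes.age_band_index(agent.age_on(day)))]
    row = table[
        (table["ethnicity"] == agent.ethnicity)
        & (table["sex"] == agent.sex)
        & (table["age_band"] == band)
        & (table["duration_stage"] == codes.DURATION_STAGE_LABELS[stage])
    ]
    if row.empty:
        raise KeyError(
            f"no competing-risks row for ({agent.ethnicity}, {agent.sex}, {band}, stage {stage})"
        )
    return float(row["h_esrd"].iloc[0]), float(row["h_death"].iloc[0])


def competing_risk_step(agent, table, day: _dt.date, rng: np.random.Generator) -> str:
    """One daily Bernoulli competing-risks update for a pre-ESRD agent."""
    if agent.state != "DM_no_ESRD":
        raise ValueError(f"agent {agent.id} is in state {agent.state}, not DM_no_ESRD")
    h_esrd, h_death = lookup_hazards(table, agent, day)
    total = h_esrd + h_death
    if total == 0:
        return NO_EVENT
    if rng.random() >= -np.expm1(-total):
        return NO_EVENT
    return ESRD_ONSET if rng.random() < h_esrd / total else DEATH
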