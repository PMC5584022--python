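"""Synthetic parameter bundles.

The original model was parameterized from Saskatchewan Ministry of Health
administrative data, CIHI special data requests and CORR annual reports,
none of which are publicly available. This module generates a complete
synthetic stand-in bundle with the same schemas and the documented structural
properties: the 1980-2005 incidence schedule sums exactly to the published
cohort sizes (8,275 First Nations; 82,306 non-First Nations, times ``scale``),
First Nations ESRD hazards exceed non-First Nations hazards, dialysis
mortality exceeds transplant mortality in every stratum, and per-patient-year
costs order HD > PD > maintained transplant.

All other numeric choices are plausible values for this system, not
published ones; see docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import codes
from ._time import N_PERIODS
from .parameters import CalibratedParameters, CostSchedule, ParameterBundle

# published 1980-2005 incident-diabetes cohort sizes
FN_COHORT_1980_2005 = 8_275
NONFN_COHORT_1980_2005 = 82_306

INCIDENCE_YEARS = np.arange(1980, 2026)
_N_HISTORIC = 26  # 1980..2005


def round_half_up(x: float) -> int:
    """Scaled totals round half away from zero (documented rounding policy)."""
    return int(np.floor(x + 0.5))


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer units proportionally to ``weights``.

    Hamilton's method: floor the exact quotas, then hand remaining units to
    the largest fractional remainders (ties to the lower index). The result
    always sums exactly to ``total``.
    """
    weights = np.asarray(weights, dtype=float)
    if total == 0 or weights.sum() == 0:
        return np.zeros(len(weights), dtype=int)
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    if short:
        order = np.lexsort((np.arange(len(weights)), -(quota - base)))
        base[order[:short]] += 1
    return base


def _year_weights(rng: np.random.Generator, growth: float) -> np.ndarray:
    """Rising epidemic trend with mild year-to-year noise."""
    trend = 1.0 + growth * (INCIDENCE_YEARS - 1980)
    jitter = np.exp(rng.normal(0.0, 0.03, size=len(INCIDENCE_YEARS)))
    return trend * jitter


def _age_sex_weights(peak_band: int, female_share: float) -> np.ndarray:
    """(sex, age_band) cell weights: triangular age profile around a peak."""
    bands = np.arange(codes.N_AGE_BANDS)
    age_w = np.maximum(0.08, 1.0 - 0.13 * np.abs(bands - peak_band))
    sex_w = np.array([1.0 - female_share, female_share])
    return sex_w[:, None] * age_w[None, :]


def _incidence_schedule(rng: np.random.Generator, scale: float) -> pd.DataFrame:
    rows = []
    specs = {
        "FN": (FN_COHORT_1980_2005, 0.06, 5, 0.55),   # younger onset, more female
        "nonFN": (NONFN_COHORT_1980_2005, 0.05, 7, 0.48),
    }
    for eth, (cohort, growth, peak, female) in specs.items():
        wy = _year_weights(rng, growth)
        target = round_half_up(scale * cohort)
        historic = largest_remainder(wy[:_N_HISTORIC], target)
        # projected years continue the same per-year trend level
        base = target / wy[:_N_HISTORIC].sum() if wy[:_N_HISTORIC].sum() else 0.0
        projected = np.array([round_half_up(base * w) for w in wy[_N_HISTORIC:]])
        yearly = np.concatenate([historic, projected])
        cell_w = _age_sex_weights(peak, female).ravel()
        for year, n in zip(INCIDENCE_YEARS, yearly):
            cells = largest_remainder(cell_w, int(n))
            k = 0
            for sex in codes.SEXES:
                for band in codes.INCIDENCE_AGE_BANDS:
                    rows.append((int(year), eth, sex, band, int(cells[k])))
                    k += 1
    return pd.DataFrame(rows, columns=["year", "ethnicity", "sex", "age_band", "count"])


def _competing_risks() -> pd.DataFrame:
    rows = []
    esrd_base = {"FN": 1.8e-5, "nonFN": 0.6e-5}  # FN disparity preserved
    for eth in codes.ETHNICITIES:
        for sex in codes.SEXES:
            for b, band in enumerate(codes.INCIDENCE_AGE_BANDS):
                for s, stage in enumerate(codes.DURATION_STAGE_LABELS):
                    h_esrd = esrd_base[eth] * 1.2**s * (1.1 if sex == "M" else 1.0)
                    h_death = (
                        6e-6 * 1.28**b
                        * (1.25 if eth == "FN" else 1.0)
                        * (1.15 if sex == "M" else 1.0)
                    )
                    rows.append((eth, sex, band, stage, h_esrd, h_death))
    return pd.DataFrame(
        rows, columns=["ethnicity", "sex", "age_band", "duration_stage", "h_esrd", "h_death"]
    )


_DIAL_TIME_FACTOR = {"0-90d": 1.35, "90d-1y": 1.10, "1-3y": 1.00, "3-5y": 1.05, "5y+": 1.15}
# transplant mortality: early surgical excess, then well below dialysis —
# 0.45 x the dialysis base keeps every transplant stratum below every
# matching dialysis stratum while leaving a realistic survival advantage
_TX_STAGE_FACTOR = {"stage1": 2.0, "stage2": 1.0, "stage3": 0.8}
_TX_BASE_FACTOR = 0.45


def _mortality() -> pd.DataFrame:
    """Per-day RRT mortality hazards; transplant < dialysis in every stratum."""
    rows = []
    for eth in codes.ETHNICITIES:
        for sex in codes.SEXES:
            for b, band in enumerate(codes.MORTALITY_AGE_BANDS):
                base = (
                    3.2e-4 * (1.0 + 0.06 * b)
                    * (1.12 if eth == "FN" else 1.0)
                    * (1.08 if sex == "M" else 1.0)
                )
                for mod, mod_f in (("HD", 1.0), ("PD", 0.95)):
                    for tb, tf in _DIAL_TIME_FACTOR.items():
                        rows.append((mod, "diabetic", eth, sex, band, tb, base * mod_f * tf))
                for st, sf in _TX_STAGE_FACTOR.items():
                    rows.append(("TX", "diabetic", eth, sex, band, st, _TX_BASE_FACTOR * base * sf))
    return pd.DataFrame(
        rows,
        columns=[
            "modality", "diabetes_status", "ethnicity", "sex",
            "age_start_band", "time_band", "hazard_per_day",
        ],
    )


def _graft_survival() -> pd.DataFrame:
    base = {
        "living": np.array([0.971, 0.952, 0.912, 0.861]),
        "deceased": np.array([0.949, 0.908, 0.848, 0.782]),
    }
    rows = []
    for donor, s in base.items():
        for g, group in enumerate(codes.GRAFT_AGE_GROUPS):
            sg = s ** (1.0 + 0.15 * g)  # worse graft survival at older recipient age
            rows.append((donor, group, *np.round(sg, 6)))
    return pd.DataFrame(
        rows, columns=["donor_type", "age_group", *codes.GRAFT_SURVIVAL_COLUMNS]
    )


def _prevalent_pools(scale: float) -> pd.DataFrame:
    """1980 prevalent pools: with-ESRD (tiny) and without-ESRD (large)."""
    sizes = {
        ("dm_esrd_1980", "FN"): 5,
        ("dm_esrd_1980", "nonFN"): 15,
        ("dm_no_esrd_1980", "FN"): 2_600,
        ("dm_no_esrd_1980", "nonFN"): 21_400,
    }
    rows = []
    for (group, eth), n in sizes.items():
        total = round_half_up(scale * n)
        per_sex = largest_remainder(np.array([0.52, 0.48]), total)
        for sex, c in zip(codes.SEXES, per_sex):
            rows.append((group, eth, sex, int(c)))
    return pd.DataFrame(rows, columns=["group", "ethnicity", "sex", "count"])


def generate_fixture_bundle(seed: int, scale: float = 1.0) -> ParameterBundle:
    """Complete, valid synthetic bundle.

    ``scale`` shrinks the population (cohort totals, prevalent pools and the
    population-proportional deceased-donor arrival rate) for fast runs;
    per-agent hazards are scale-free. Same seed, same bundle, byte for byte.
    """
    if not (0 < scale <= 1):
        raise ValueError(f"scale must be in (0, 1], got {scale}")
    rng = np.random.default_rng(seed)

    years_mod = np.arange(1981, 2012)
    modality = pd.DataFrame(
        {"year": years_mod, "p_pd_initial": np.round(0.42 - 0.006 * (years_mod - 1981), 6)}
    )
    years_don = np.arange(1981, 2000)
    donor = pd.DataFrame(
        {"year": years_don, "p_living": np.round(0.20 + 0.01 * (years_don - 1981), 6)}
    )
    switching = pd.DataFrame(
        {"direction": ["hd_to_pd", "pd_to_hd"], "hazard_per_day": [5e-5, 2.5e-4]}
    )
    costs = CostSchedule(
        annual={
            "HD": 95_000.0,
            "PD": 56_000.0,
            "TX_stage1": 130_000.0,
            "TX_stage2": 60_000.0,
            "TX_stage3": 22_000.0,
        },
        transplant_event=60_000.0,
        living_donor_surcharge=15_000.0,
        discount_rate=0.03,
        base_year=2008,
    )
    calibrated = CalibratedParameters(
        withdrawal_rate=5e-4,
        eligibility_cutoff=0.3,
        assessment_appointments=4,
        assessment_mean_days_per_test=30.0,
        preemptive_transplant_probability=0.05,
        preemptive_living_fraction=0.6,
        # survival on dialysis improves over calendar time; anchored to 1
        # in the 2005-09 interval where the source survival model sits
        period_mortality_multipliers=np.array(
            [1.35, 1.27, 1.20, 1.13, 1.06, 1.00, 0.94, 0.89, 0.84][:N_PERIODS]
        ),
    )
    bundle = ParameterBundle(
        incidence=_incidence_schedule(rng, scale),
        modality_probability=modality,
        donor_type=donor,
        graft_survival=_graft_survival(),
        competing_risks=_competing_risks(),
        mortality=_mortality(),
        switching=switching,
        costs=costs,
        calibrated=calibrated,
        initial_modality={"HD": 0.55, "PD": 0.25, "TX": 0.20},
        transplant_rates={"living": 2.0e-3, "deceased": 0.020 * scale},
        prevalent_pools=_prevalent_pools(scale),
    )
    return bundle
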