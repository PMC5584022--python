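"""Integer codings and label vocabularies shared across modules.

Covariates are stored as small integers inside the engine; these tables fix
the code <-> label mapping used by every CSV schema and by the event log.
"""

from __future__ import annotations

import numpy as np

# --- ethnicity / sex -------------------------------------------------------
ETHNICITIES = ("FN", "nonFN")
SEXES = ("M", "F")
ETH_CODE = {s: i for i, s in enumerate(ETHNICITIES)}
SEX_CODE = {s: i for i, s in enumerate(SEXES)}

# --- treatment states ------------------------------------------------------
DM, HD, PD, TX, DEAD, EXITED = range(6)
STATE_LABELS = ("DM_no_ESRD", "HD", "PD", "Transplant", "Dead", "Exited")
DIALYSIS_STATES = (HD, PD)

# transplant-pathway stage (orthogonal to the treatment state: an agent under
# assessment or on the waiting list is still dialysing)
PW_NONE, PW_ASSESSMENT, PW_WAITLIST, PW_INELIGIBLE, PW_DECLINED, PW_POSTTX, PW_WITHDRAWN = range(7)
PATHWAY_LABELS = (
    "none", "Assessment", "Waitlist", "ineligible", "declined", "post_transplant", "withdrawn",
)

# --- age bands -------------------------------------------------------------
# incidence / progression bands: 5-year, 20-24 ... 80-84, then 85+
INCIDENCE_AGE_BANDS = tuple(f"{a}-{a + 4}" for a in range(20, 85, 5)) + ("85+",)
N_AGE_BANDS = len(INCIDENCE_AGE_BANDS)  # 14

# treatment mortality bands: 5-year 20-74, then 75+
MORTALITY_AGE_BANDS = tuple(f"{a}-{a + 4}" for a in range(20, 75, 5)) + ("75+",)
N_MORT_AGE_BANDS = len(MORTALITY_AGE_BANDS)  # 12

# graft-failure recipient age groups
GRAFT_AGE_GROUPS = ("18-44", "45-54", "55-64", "65+")
N_GRAFT_AGE_GROUPS = 4

DONOR_TYPES = ("living", "deceased")
DONOR_CODE = {s: i for i, s in enumerate(DONOR_TYPES)}
LIVING, DECEASED = 0, 1

# --- time-on-treatment bands ----------------------------------------------
DIALYSIS_TIME_BANDS = ("0-90d", "90d-1y", "1-3y", "3-5y", "5y+")
DIALYSIS_TIME_EDGES = np.array([0, 90, 365, 1095, 1825])  # band i: [edge_i, edge_{i+1})
TX_STAGES = ("stage1", "stage2", "stage3")  # <=90d, 90d-1y, >1y post transplant

# graft-survival measurement points, in days post transplant
GRAFT_INTERVAL_EDGES = np.array([0, 90, 365, 1095, 1825])
GRAFT_SURVIVAL_COLUMNS = ("s_90d", "s_1y", "s_3y", "s_5y")

# competing-risks duration stages: 3-year bands, capped at >=24 years
N_DURATION_STAGES = 9
DURATION_STAGE_LABELS = tuple(f"{3 * i}-{3 * i + 3}y" for i in range(8)) + (">=24y",)

COSTED_STATE_KEYS = ("HD", "PD", "TX_stage1", "TX_stage2", "TX_stage3")


def age_band_index(age: np.ndarray | int) -> np.ndarray:
    """5-year incidence/progression band index from completed age (>=20)."""
    return np.minimum(np.maximum((np.asarray(age) - 20) // 5, 0), N_AGE_BANDS - 1)


def mortality_age_band_index(age: np.ndarray | int) -> np.ndarray:
    return np.minimum(np.maximum((np.asarray(age) - 20) // 5, 0), N_MORT_AGE_BANDS - 1)


def graft_age_group_index(age: np.ndarray | int) -> np.ndarray:
    age = np.asarray(age)
    return np.digitize(age, [45, 55, 65])


def dialysis_time_band_index(days_on: np.ndarray | int) -> np.ndarray:
    return np.minimum(
        np.searchsorted(DIALYSIS_TIME_EDGES, np.asarray(days_on), side="right") - 1,
        len(DIALYSIS_TIME_BANDS) - 1,
    )


def tx_stage_index(days_since_tx: np.ndarray | int) -> np.ndarray:
    """Post-transplant stage: 0 for day<=90, 1 for 90<day<=365, 2 beyond."""
    d = np.asarray(days_since_tx)
    return (d > 90).astype(np.int64) + (d > 365).astype(np.int64)
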