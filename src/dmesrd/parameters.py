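"""Parameter tables: domain types, validation, and delimited-text round trip.

A :class:`ParameterBundle` carries every input the simulator needs, one
headered CSV per table plus a small YAML manifest. Validation enumerates all
schema violations (naming table and row) instead of silently coercing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import codes
from ._time import FIRST_YEAR, LAST_YEAR, N_PERIODS, PERIOD_STARTS

SCHEMA_VERSION = 1

TABLE_FILES = {
    "incidence": "incidence.csv",
    "modality_probability": "modality_probability.csv",
    "donor_type": "donor_type.csv",
    "graft_survival": "graft_survival.csv",
    "competing_risks": "competing_risks.csv",
    "mortality": "mortality.csv",
    "switching": "switching.csv",
    "costs": "costs.csv",
    "calibrated": "calibrated.csv",
    "period_multipliers": "period_multipliers.csv",
    "initial_modality": "initial_modality.csv",
    "transplant_rates": "transplant_rates.csv",
    "prevalent_pools": "prevalent_pools.csv",
}


class ParameterValidationError(ValueError):
    """Raised by :func:`load_bundle` with every violation enumerated."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("parameter validation failed:\n" + "\n".join(self.problems))


@dataclass
class CostSchedule:
    """Annual treatment costs in 2008 CAD plus the discounting convention.

    ``annual`` maps the five costed states (HD, PD, three post-transplant
    stages) to cost per year; ``transplant_event`` is booked once on the day
    of surgery, with ``living_donor_surcharge`` added for living donors
    (extra donor evaluation). Discounting is whole-calendar-year at
    ``discount_rate`` around ``base_year``.
    """

    annual: dict[str, float]
    transplant_event: float
    living_donor_surcharge: float
    discount_rate: float = 0.03
    base_year: int = 2008


@dataclass
class CalibratedParameters:
    """The five parameters the original model estimated by calibration."""

    withdrawal_rate: float  # per-day hazard of leaving the waiting list
    eligibility_cutoff: float  # health-coefficient threshold in [0, 1]
    assessment_appointments: int  # Erlang shape (number of tests)
    assessment_mean_days_per_test: float  # Erlang mean = shape * this
    preemptive_transplant_probability: float
    preemptive_living_fraction: float  # living share of pre-emptive grafts
    period_mortality_multipliers: np.ndarray = field(
        default_factory=lambda: np.ones(N_PERIODS)
    )  # multiplicative factor on dialysis mortality per 5-year interval

    def replace(self, **kw) -> "CalibratedParameters":
        return dataclasses.replace(self, **kw)


@dataclass
class ParameterBundle:
    """Every parameter table the simulator consumes, already validated."""

    incidence: pd.DataFrame  # year, ethnicity, sex, age_band, count
    modality_probability: pd.DataFrame  # year, p_pd_initial
    donor_type: pd.DataFrame  # year, p_living
    graft_survival: pd.DataFrame  # donor_type, age_group, s_90d..s_5y
    competing_risks: pd.DataFrame  # ethnicity, sex, age_band, duration_stage, h_esrd, h_death
    mortality: pd.DataFrame  # modality, diabetes_status, ethnicity, sex, age_start_band, time_band, hazard_per_day
    switching: pd.DataFrame  # direction, hazard_per_day
    costs: CostSchedule
    calibrated: CalibratedParameters
    initial_modality: dict[str, float]  # 1980 prevalent-pool split over HD/PD/TX
    transplant_rates: dict[str, float]  # living, deceased: per-day event rates
    prevalent_pools: pd.DataFrame  # group, ethnicity, sex, count
    schema_version: int = SCHEMA_VERSION

    def with_calibrated(self, calibrated: CalibratedParameters) -> "ParameterBundle":
        return dataclasses.replace(self, calibrated=calibrated)


# ---------------------------------------------------------------------------
# nearest-year lookup


def nearest_year_value(table: pd.DataFrame, year: int, value_col: str) -> float:
    """Value for ``year``, clamped to the nearest covered year.

    Outside the covered span this clamps to the first/last year (never
    extrapolates); interior gaps resolve to the closest year, ties toward
    the earlier year.
    """
    years = table["year"].to_numpy()
    order = np.argsort(years, kind="stable")
    years = years[order]
    vals = table[value_col].to_numpy()[order]
    dist = np.abs(years - year)
    # stable argmin prefers the earlier year on ties
    return float(vals[int(np.argmin(dist))])


# ---------------------------------------------------------------------------
# validation


def _check_prob(problems, name, df, col):
    bad = df.index[(df[col] < 0) | (df[col] > 1)]
    for i in bad:
        problems.append(f"{name} row {i}: {col}={df.loc[i, col]} outside [0, 1]")


def _check_nonneg(problems, name, df, col):
    bad = df.index[df[col] < 0]
    for i in bad:
        problems.append(f"{name} row {i}: {col}={df.loc[i, col]} negative")


def _check_unique_keys(problems, name, df, keys):
    dup = df.duplicated(subset=list(keys))
    for i in df.index[dup]:
        problems.append(f"{name} row {i}: duplicate key {tuple(df.loc[i, k] for k in keys)}")


def _check_levels(problems, name, df, col, allowed):
    bad = df.index[~df[col].isin(allowed)]
    for i in bad:
        problems.append(f"{name} row {i}: {col}={df.loc[i, col]!r} not in {sorted(allowed)}")


def validate_bundle(bundle: ParameterBundle) -> list[str]:
    """Every schema violation in the bundle, as human-readable strings."""
    p: list[str] = []

    inc = bundle.incidence
    _check_levels(p, "incidence", inc, "ethnicity", codes.ETHNICITIES)
    _check_levels(p, "incidence", inc, "sex", codes.SEXES)
    _check_levels(p, "incidence", inc, "age_band", codes.INCIDENCE_AGE_BANDS)
    _check_nonneg(p, "incidence", inc, "count")
    _check_unique_keys(p, "incidence", inc, ("year", "ethnicity", "sex", "age_band"))
    years = np.sort(inc["year"].unique())
    if len(years):
        if years[0] < FIRST_YEAR or years[-1] > LAST_YEAR:
            p.append(f"incidence: years span {years[0]}-{years[-1]}, outside {FIRST_YEAR}-{LAST_YEAR}")
        gaps = np.setdiff1d(np.arange(years[0], years[-1] + 1), years)
        if len(gaps):
            p.append(f"incidence: years not contiguous, missing {list(gaps)}")
    else:
        p.append("incidence: empty table")

    for name, col in (("modality_probability", "p_pd_initial"), ("donor_type", "p_living")):
        df = getattr(bundle, name)
        _check_prob(p, name, df, col)
        _check_unique_keys(p, name, df, ("year",))
        if df.empty:
            p.append(f"{name}: empty table")

    gs = bundle.graft_survival
    _check_levels(p, "graft_survival", gs, "donor_type", codes.DONOR_TYPES)
    _check_levels(p, "graft_survival", gs, "age_group", codes.GRAFT_AGE_GROUPS)
    _check_unique_keys(p, "graft_survival", gs, ("donor_type", "age_group"))
    for i, row in gs.iterrows():
        s = [row[c] for c in codes.GRAFT_SURVIVAL_COLUMNS]
        if not (1 >= s[0] >= s[1] >= s[2] >= s[3] > 0):
            p.append(
                f"graft_survival row {i} (donor_type={row['donor_type']}, "
                f"age_group={row['age_group']}): survival fractions {s} not monotone in (0, 1]"
            )
    have = {(r["donor_type"], r["age_group"]) for _, r in gs.iterrows()}
    for d in codes.DONOR_TYPES:
        for a in codes.GRAFT_AGE_GROUPS:
            if (d, a) not in have:
                p.append(f"graft_survival: missing stratum (donor_type={d}, age_group={a})")

    cr = bundle.competing_risks
    _check_levels(p, "competing_risks", cr, "ethnicity", codes.ETHNICITIES)
    _check_levels(p, "competing_risks", cr, "sex", codes.SEXES)
    _check_levels(p, "competing_risks", cr, "age_band", codes.INCIDENCE_AGE_BANDS)
    _check_levels(p, "competing_risks", cr, "duration_stage", codes.DURATION_STAGE_LABELS)
    _check_nonneg(p, "competing_risks", cr, "h_esrd")
    _check_nonneg(p, "competing_risks", cr, "h_death")
    _check_unique_keys(p, "competing_risks", cr, ("ethnicity", "sex", "age_band", "duration_stage"))
    n_expect = 2 * 2 * codes.N_AGE_BANDS * codes.N_DURATION_STAGES
    if len(cr.drop_duplicates(["ethnicity", "sex", "age_band", "duration_stage"])) < n_expect:
        p.append(f"competing_risks: expected {n_expect} strata, found {len(cr)}")

    mt = bundle.mortality
    _check_levels(p, "mortality", mt, "modality", ("HD", "PD", "TX"))
    _check_levels(p, "mortality", mt, "ethnicity", codes.ETHNICITIES)
    _check_levels(p, "mortality", mt, "sex", codes.SEXES)
    _check_levels(p, "mortality", mt, "age_start_band", codes.MORTALITY_AGE_BANDS)
    _check_nonneg(p, "mortality", mt, "hazard_per_day")
    dial = mt[mt["modality"].isin(("HD", "PD"))]
    _check_levels(p, "mortality", dial, "time_band", codes.DIALYSIS_TIME_BANDS)
    tx = mt[mt["modality"] == "TX"]
    _check_levels(p, "mortality", tx, "time_band", codes.TX_STAGES)
    _check_unique_keys(p, "mortality", mt, ("modality", "ethnicity", "sex", "age_start_band", "time_band"))
    n_expect = (2 * len(codes.DIALYSIS_TIME_BANDS) + len(codes.TX_STAGES)) * 2 * 2 * codes.N_MORT_AGE_BANDS
    if len(mt) < n_expect:
        p.append(f"mortality: expected {n_expect} strata, found {len(mt)}")

    sw = bundle.switching
    _check_levels(p, "switching", sw, "direction", ("hd_to_pd", "pd_to_hd"))
    _check_nonneg(p, "switching", sw, "hazard_per_day")

    cs = bundle.costs
    for k in codes.COSTED_STATE_KEYS:
        if k not in cs.annual:
            p.append(f"costs: missing annual cost for state {k}")
        elif cs.annual[k] < 0:
            p.append(f"costs: annual cost for {k} negative")
    if cs.transplant_event < 0 or cs.living_donor_surcharge < 0:
        p.append("costs: one-time transplant costs must be >= 0")
    if not (0 <= cs.discount_rate < 1):
        p.append(f"costs: discount_rate {cs.discount_rate} outside [0, 1)")

    cal = bundle.calibrated
    if cal.withdrawal_rate < 0:
        p.append("calibrated: withdrawal_rate negative")
    if not (0 <= cal.eligibility_cutoff <= 1):
        p.append("calibrated: eligibility_cutoff outside [0, 1]")
    if cal.assessment_appointments < 1:
        p.append("calibrated: assessment_appointments must be a positive integer")
    if cal.assessment_mean_days_per_test <= 0:
        p.append("calibrated: assessment_mean_days_per_test must be positive")
    for nm in ("preemptive_transplant_probability", "preemptive_living_fraction"):
        v = getattr(cal, nm)
        if not (0 <= v <= 1):
            p.append(f"calibrated: {nm}={v} outside [0, 1]")
    mult = np.asarray(cal.period_mortality_multipliers, dtype=float)
    if mult.shape != (N_PERIODS,):
        p.append(f"calibrated: expected {N_PERIODS} period multipliers, got {mult.shape}")
    elif np.any(mult <= 0):
        p.append("calibrated: period mortality multipliers must be positive")

    im = bundle.initial_modality
    if set(im) != {"HD", "PD", "TX"}:
        p.append(f"initial_modality: states {sorted(im)} != ['HD', 'PD', 'TX']")
    elif abs(sum(im.values()) - 1.0) > 1e-9 or min(im.values()) < 0:
        p.append(f"initial_modality: probabilities {im} must be >= 0 and sum to 1")

    tr = bundle.transplant_rates
    if set(tr) != {"living", "deceased"}:
        p.append(f"transplant_rates: donor types {sorted(tr)} != ['deceased', 'living']")
    elif min(tr.values()) < 0:
        p.append("transplant_rates: rates must be >= 0")

    pools = bundle.prevalent_pools
    _check_levels(p, "prevalent_pools", pools, "group", ("dm_esrd_1980", "dm_no_esrd_1980"))
    _check_levels(p, "prevalent_pools", pools, "ethnicity", codes.ETHNICITIES)
    _check_levels(p, "prevalent_pools", pools, "sex", codes.SEXES)
    _check_nonneg(p, "prevalent_pools", pools, "count")
    _check_unique_keys(p, "prevalent_pools", pools, ("group", "ethnicity", "sex"))

    return p


# ---------------------------------------------------------------------------
# save / load


def save_bundle(bundle: ParameterBundle, path: str | Path) -> Path:
    """Write one CSV per table plus ``manifest.yaml``; returns the directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    frames = {
        "incidence": bundle.incidence,
        "modality_probability": bundle.modality_probability,
        "donor_type": bundle.donor_type,
        "graft_survival": bundle.graft_survival,
        "competing_risks": bundle.competing_risks,
        "mortality": bundle.mortality,
        "switching": bundle.switching,
        "prevalent_pools": bundle.prevalent_pools,
    }
    for name, df in frames.items():
        df.to_csv(path / TABLE_FILES[name], index=False)

    cost_rows = [("item", "value")]
    for k in codes.COSTED_STATE_KEYS:
        cost_rows.append((f"annual_{k}", bundle.costs.annual[k]))
    cost_rows += [
        ("transplant_event", bundle.costs.transplant_event),
        ("living_donor_surcharge", bundle.costs.living_donor_surcharge),
        ("discount_rate", bundle.costs.discount_rate),
        ("base_year", bundle.costs.base_year),
    ]
    _write_kv(path / TABLE_FILES["costs"], cost_rows)

    cal = bundle.calibrated
    _write_kv(
        path / TABLE_FILES["calibrated"],
        [
            ("parameter", "value"),
            ("withdrawal_rate_per_day", cal.withdrawal_rate),
            ("eligibility_cutoff", cal.eligibility_cutoff),
            ("assessment_appointments", cal.assessment_appointments),
            ("assessment_mean_days_per_test", cal.assessment_mean_days_per_test),
            ("preemptive_transplant_probability", cal.preemptive_transplant_probability),
            ("preemptive_living_fraction", cal.preemptive_living_fraction),
        ],
    )
    pd.DataFrame(
        {
            "period_start": PERIOD_STARTS,
            "multiplier": np.asarray(cal.period_mortality_multipliers, dtype=float),
        }
    ).to_csv(path / TABLE_FILES["period_multipliers"], index=False)

    _write_kv(
        path / TABLE_FILES["initial_modality"],
        [("state", "probability")] + [(k, bundle.initial_modality[k]) for k in ("HD", "PD", "TX")],
    )
    _write_kv(
        path / TABLE_FILES["transplant_rates"],
        [("donor_type", "rate_per_day")]
        + [(k, bundle.transplant_rates[k]) for k in ("living", "deceased")],
    )

    manifest = {
        "schema_version": bundle.schema_version,
        "tables": dict(TABLE_FILES),
    }
    (path / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return path


def _write_kv(file: Path, rows) -> None:
    file.write_text("\n".join(f"{a},{b!r}" if isinstance(b, float) else f"{a},{b}" for a, b in rows) + "\n")


def load_bundle(path: str | Path) -> ParameterBundle:
    """Load and validate a bundle directory written by :func:`save_bundle`.

    Raises :class:`ParameterValidationError` listing every violation, or
    ``FileNotFoundError`` naming the first missing table.
    """
    path = Path(path)
    manifest_file = path / "manifest.yaml"
    if not manifest_file.exists():
        raise FileNotFoundError(f"no manifest.yaml in {path}")
    manifest = yaml.safe_load(manifest_file.read_text())
    tables = manifest.get("tables", TABLE_FILES)
    for name, fname in tables.items():
        if not (path / fname).exists():
            raise FileNotFoundError(f"missing parameter table {name!r}: {path / fname}")

    def read(name):
        return pd.read_csv(path / tables[name])

    costs_kv = dict(read("costs").itertuples(index=False))
    costs = CostSchedule(
        annual={k: float(costs_kv[f"annual_{k}"]) for k in codes.COSTED_STATE_KEYS},
        transplant_event=float(costs_kv["transplant_event"]),
        living_donor_surcharge=float(costs_kv["living_donor_surcharge"]),
        discount_rate=float(costs_kv["discount_rate"]),
        base_year=int(float(costs_kv["base_year"])),
    )
    cal_kv = dict(read("calibrated").itertuples(index=False))
    mult = read("period_multipliers").sort_values("period_start")["multiplier"].to_numpy(float)
    calibrated = CalibratedParameters(
        withdrawal_rate=float(cal_kv["withdrawal_rate_per_day"]),
        eligibility_cutoff=float(cal_kv["eligibility_cutoff"]),
        assessment_appointments=int(float(cal_kv["assessment_appointments"])),
        assessment_mean_days_per_test=float(cal_kv["assessment_mean_days_per_test"]),
        preemptive_transplant_probability=float(cal_kv["preemptive_transplant_probability"]),
        preemptive_living_fraction=float(cal_kv["preemptive_living_fraction"]),
        period_mortality_multipliers=mult,
    )
    im = dict(read("initial_modality").itertuples(index=False))
    tr = dict(read("transplant_rates").itertuples(index=False))

    bundle = ParameterBundle(
        incidence=read("incidence"),
        modality_probability=read("modality_probability"),
        donor_type=read("donor_type"),
        graft_survival=read("graft_survival"),
        competing_risks=read("competing_risks"),
        mortality=read("mortality"),
        switching=read("switching"),
        costs=costs,
        calibrated=calibrated,
        initial_modality={k: float(v) for k, v in im.items()},
        transplant_rates={k: float(v) for k, v in tr.items()},
        prevalent_pools=read("prevalent_pools"),
        schema_version=int(manifest.get("schema_version", SCHEMA_VERSION)),
    )
    problems = validate_bundle(bundle)
    if problems:
        raise ParameterValidationError(problems)
    return bundle


def bundles_equal(a: ParameterBundle, b: ParameterBundle) -> bool:
    """Content equality (frame-by-frame, scalar-by-scalar)."""
    frames = (
        "incidence", "modality_probability", "donor_type", "graft_survival",
        "competing_risks", "mortality", "switching", "prevalent_pools",
    )
    for name in frames:
        fa, fb = getattr(a, name), getattr(b, name)
        try:
            pd.testing.assert_frame_equal(
                fa.reset_index(drop=True), fb.reset_index(drop=True), check_dtype=False
            )
        except AssertionError:
            return False
    if a.costs != b.costs or a.initial_modality != b.initial_modality:
        return False
    if a.transplant_rates != b.transplant_rates:
        return False
    ca, cb = a.calibrated, b.calibrated
    if not np.allclose(ca.period_mortality_multipliers, cb.period_mortality_multipliers):
        return False
    for f in (
        "withdrawal_rate", "eligibility_cutoff", "assessment_appointments",
        "assessment_mean_days_per_test", "preemptive_transplant_probability",
        "preemptive_living_fraction",
    ):
        if getattr(ca, f) != getattr(cb, f):
            return False
    return True
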