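"""Engine: daily loop bookkeeping, scenarios, summaries, reproducibility."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import dmesrd as dm
from dmesrd.engine import (
    ScenarioConfig,
    apply_scenario,
    run_realization,
    run_scenario,
    summarize_realizations,
)
from dmesrd._time import date_to_day
import datetime as dt


@pytest.fixture(scope="module")
def zero_bundle(bundle_small):
    inc = bundle_small.incidence.copy()
    inc["count"] = 0
    pools = bundle_small.prevalent_pools.copy()
    pools["count"] = 0
    return dataclasses.replace(bundle_small, incidence=inc, prevalent_pools=pools)


def test_empty_population_gives_all_zero_summaries(zero_bundle):
    out = run_realization(zero_bundle, ScenarioConfig(master_seed=0, end_year=1985), 0)
    numeric = out.yearly.drop(columns="year")
    assert (numeric.to_numpy() == 0).all()
    assert len(out.events) == 0


def test_same_seed_reproduces_event_log(bundle_small):
    cfg = ScenarioConfig(master_seed=42, end_year=1995)
    a = run_realization(bundle_small, cfg, 0)
    b = run_realization(bundle_small, cfg, 0)
    pd.testing.assert_frame_equal(a.events, b.events)
    pd.testing.assert_frame_equal(a.yearly, b.yearly)
    assert a.metadata == b.metadata


def test_different_realizations_differ(bundle_small):
    cfg = ScenarioConfig(master_seed=42, end_year=1995)
    a = run_realization(bundle_small, cfg, 0)
    b = run_realization(bundle_small, cfg, 1)
    assert not a.yearly.equals(b.yearly)


def test_agent_conservation(baseline_run):
    """Every agent who entered is alive, dead, or exited at the end."""
    md = baseline_run.metadata
    entered = (baseline_run.events.cause == "entry").sum()
    assert entered == md["agents_created"]
    assert entered == md["agents_alive_at_end"] + md["agents_dead"] + md["agents_exited"]


def test_prevalence_bookkeeping_identity(baseline_run):
    """prev[y] = prev[y-1] + incident[y] - ESRD deaths[y], every year."""
    y = baseline_run.yearly.set_index("year")
    for year in range(1981, 2026):
        expect = (
            y.loc[year - 1, "prev_total"]
            + y.loc[year, "incident_esrd"]
            - y.loc[year, "deaths_esrd"]
        )
        assert y.loc[year, "prev_total"] == expect, year


def test_no_events_outside_agent_lifespan(baseline_run):
    ev = baseline_run.events
    first = ev[ev.cause == "entry"].groupby("agent_id")["day"].min()
    deaths = ev[ev.cause == "death"].groupby("agent_id")["day"].min()
    by_agent = ev.groupby("agent_id")["day"]
    assert (by_agent.min() >= first.reindex(by_agent.min().index)).all()
    last = by_agent.max()
    common = deaths.index
    assert (last.loc[common] <= deaths).all()


def test_dead_is_absorbing(baseline_run):
    ev = baseline_run.events
    from_dead = ev[ev.from_state == "Dead"]
    assert len(from_dead) == 0


def test_unknown_scenario_rejected():
    with pytest.raises(ValueError, match="unknown scenario"):
        ScenarioConfig(scenario="mystery")


def test_scenario1_stops_new_diagnoses(bundle_tiny, s1_run):
    agents = s1_run.agents
    cutoff = date_to_day(dt.date(2006, 1, 1))
    assert (agents.dm_diagnosis_day < cutoff).all()
    # the schedule itself was zeroed, nothing else touched
    adj, _ = apply_scenario(
        ScenarioConfig(scenario="no_new_dm_after_2005"), bundle_tiny
    )
    assert adj.incidence.loc[adj.incidence.year >= 2006, "count"].sum() == 0
    pd.testing.assert_frame_equal(
        adj.incidence[adj.incidence.year < 2006],
        bundle_tiny.incidence[bundle_tiny.incidence.year < 2006],
    )


def test_scenario2_transplants_every_onset(s2_run):
    ev = s2_run.events
    assert (ev.cause == "esrd_onset").sum() == 0  # nobody starts dialysis at onset
    n_pre = (ev.cause == "preemptive_transplant").sum()
    assert n_pre == s2_run.yearly.incident_esrd.sum()


def test_scenario2_redialysis_gap_is_90_days(s2_run):
    ev = s2_run.events
    failures = ev[ev.cause == "graft_failure"][["agent_id", "day"]]
    retx = ev[ev.cause == "retransplant"][["agent_id", "day"]]
    gaps = []
    for aid, grp in failures.groupby("agent_id"):
        later = retx[retx.agent_id == aid]
        for d in grp.day:
            nxt = later.day[later.day > d]
            if len(nxt):
                gaps.append(int(nxt.min() - d))
    assert len(gaps) > 10
    assert set(gaps) == {90}


def test_ineligible_agents_never_transplanted_outside_s2(baseline_run, bundle_tiny):
    ev = baseline_run.events
    cutoff = bundle_tiny.calibrated.eligibility_cutoff
    flagged = set(ev.loc[ev.cause == "ineligible", "agent_id"])
    tx_causes = {"transplant"}  # waitlist transplants require eligibility
    transplanted = set(ev.loc[ev.cause.isin(tx_causes), "agent_id"])
    assert flagged.isdisjoint(transplanted)
    agents = baseline_run.agents.set_index("agent_id")
    assert (agents.loc[sorted(flagged), "health_coefficient"] < cutoff).all()


def test_waitlist_membership_only_changes_by_allowed_events(baseline_run):
    ev = baseline_run.events
    listings = (ev.cause == "listed").sum()
    leaves = (
        (ev.cause == "transplant").sum()
        + (ev.cause == "withdrawal").sum()
        + (ev.cause == "delisted_death").sum()
    )
    still = int(baseline_run.yearly.iloc[-1].waitlist_total)
    assert listings == leaves + still


def test_study_exit_hazard_produces_exits(bundle_small):
    cfg = ScenarioConfig(master_seed=9, end_year=1990, exit_hazard=5e-4)
    out = run_realization(bundle_small, cfg, 0)
    md = out.metadata
    assert md["agents_exited"] > 0
    entered = (out.events.cause == "entry").sum()
    assert entered == md["agents_alive_at_end"] + md["agents_dead"] + md["agents_exited"]
    assert (out.events[out.events.from_state == "Exited"]).empty


class TestSummaries:
    def test_single_realization_median_is_identity(self, baseline_run):
        stacked, summary = summarize_realizations([baseline_run])
        wide = stacked.pivot(index="year", columns="variable", values="value")
        yearly = baseline_run.yearly.set_index("year")
        assert np.allclose(wide["prev_total"], yearly["prev_total"])
        med = summary[summary.variable == "prev_total"].set_index("year")["median"]
        assert np.allclose(med, yearly["prev_total"])

    def test_constant_realizations_have_zero_iqr(self, zero_bundle):
        cfg = ScenarioConfig(master_seed=0, end_year=1983, n_realizations=2)
        stacked, summary = summarize_realizations(run_scenario(zero_bundle, cfg))
        assert np.allclose(summary.q75 - summary.q25, 0.0)

    def test_medians_match_independent_recomputation(self, bundle_small):
        cfg = ScenarioConfig(master_seed=2, end_year=1992, n_realizations=5)
        outs = run_scenario(bundle_small, cfg)
        stacked, summary = summarize_realizations(outs)
        # independent median over the raw yearly frames
        for var in ("prev_total", "cost_undiscounted"):
            raw = np.stack([o.yearly[var].to_numpy() for o in outs])
            med = np.median(raw, axis=0)
            got = (
                summary[summary.variable == var].sort_values("year")["median"].to_numpy()
            )
            assert np.allclose(got, med)

    def test_histogram_export_writes_data_and_metadata(self, tmp_path, baseline_run):
        stacked, _ = summarize_realizations([baseline_run])
        meta = dm.export_histogram_data(stacked, "prev_total", tmp_path / "h.csv")
        assert (tmp_path / "h.csv").exists()
        assert (tmp_path / "h.meta.yaml").exists()
        assert meta["realizations"] == 1


def test_run_output_save_round_trip(tmp_path, baseline_run):
    out_dir = baseline_run.save(tmp_path / "run")
    again = pd.read_csv(out_dir / "yearly_summary.csv")
    assert np.allclose(again["prev_total"], baseline_run.yearly["prev_total"])
    assert (out_dir / "run_metadata.yaml").exists()
    assert (out_dir / "events.csv").exists()
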