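"""RRT dynamics: modality choice, graft hazards, mortality, switching."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import dmesrd as dm
from dmesrd import codes
from dmesrd.population import Agent
from dmesrd.rrt import (
    MortalityHazardTable,
    SwitchingHazards,
    compile_graft_hazards,
    dialysis_switch_step,
    graft_failure_hazard,
    maybe_preemptive_transplant,
    mortality_hazard,
    select_initial_modality,
)


def agent_on(state, **kw) -> Agent:
    base = dict(
        id=0, ethnicity="FN", sex="M",
        birth_date=dt.date(1950, 1, 1), dm_diagnosis_date=dt.date(1990, 1, 1),
        health_coefficient=0.5, state=state,
        rrt_start_date=dt.date(2000, 1, 1), first_rrt_date=dt.date(2000, 1, 1),
    )
    base.update(kw)
    return Agent(**base)


class TestInitialModality:
    def test_degenerate_probabilities(self):
        rng = np.random.default_rng(0)
        always_pd = pd.DataFrame({"year": [1990], "p_pd_initial": [1.0]})
        always_hd = pd.DataFrame({"year": [1990], "p_pd_initial": [0.0]})
        assert all(select_initial_modality(1990, always_pd, rng) == "PD" for _ in range(200))
        assert all(select_initial_modality(1990, always_hd, rng) == "HD" for _ in range(200))

    def test_fraction_matches_probability(self):
        table = pd.DataFrame({"year": [1990], "p_pd_initial": [0.3]})
        rng = np.random.default_rng(1)
        n = 10_000
        pd_count = sum(select_initial_modality(1990, table, rng) == "PD" for _ in range(n))
        half = 2.576 * np.sqrt(0.3 * 0.7 / n)
        assert abs(pd_count / n - 0.3) < half

    def test_uses_nearest_year(self):
        table = pd.DataFrame({"year": [1985, 1995], "p_pd_initial": [1.0, 0.0]})
        rng = np.random.default_rng(2)
        assert select_initial_modality(1980, table, rng) == "PD"
        assert select_initial_modality(2005, table, rng) == "HD"


class TestPreemptive:
    def test_zero_probability_never_fires(self, bundle_small):
        params = bundle_small.calibrated.replace(preemptive_transplant_probability=0.0)
        rng = np.random.default_rng(0)
        a = agent_on("DM_no_ESRD")
        assert all(maybe_preemptive_transplant(a, params, rng) == "none" for _ in range(500))

    def test_living_split(self, bundle_small):
        params = bundle_small.calibrated.replace(
            preemptive_transplant_probability=0.05, preemptive_living_fraction=0.6
        )
        rng = np.random.default_rng(1)
        a = agent_on("DM_no_ESRD")
        draws = [maybe_preemptive_transplant(a, params, rng) for _ in range(100_000)]
        events = [d for d in draws if d != "none"]
        p_half = 2.576 * np.sqrt(0.05 * 0.95 / len(draws))
        assert abs(len(events) / len(draws) - 0.05) < p_half
        living = sum(d == "living" for d in events) / len(events)
        half = 2.576 * np.sqrt(0.6 * 0.4 / len(events))
        assert abs(living - 0.6) < half


def survival_table(**kw):
    rows = []
    s = dict(s_90d=0.95, s_1y=0.9, s_3y=0.8, s_5y=0.7)
    s.update(kw)
    for donor in codes.DONOR_TYPES:
        for group in codes.GRAFT_AGE_GROUPS:
            rows.append({"donor_type": donor, "age_group": group, **s})
    return pd.DataFrame(rows)


class TestGraftHazard:
    def test_perfect_survival_gives_zero_hazard(self):
        table = survival_table(s_90d=1.0, s_1y=1.0, s_3y=1.0, s_5y=1.0)
        for d in (30, 200, 700, 1500, 4000):
            assert graft_failure_hazard("living", "18-44", d, table) == 0.0

    def test_flat_tail_gives_zero_late_hazard(self):
        table = survival_table(s_90d=0.9, s_1y=0.9, s_3y=0.9, s_5y=0.9)
        assert graft_failure_hazard("deceased", "55-64", 500, table) == 0.0
        assert graft_failure_hazard("deceased", "55-64", 50, table) > 0.0

    def test_interval_formula(self):
        # (1y, 3y]: ln(0.9/0.8)/730 per day
        table = survival_table()
        expect = np.log(0.9 / 0.8) / 730.0
        assert graft_failure_hazard("living", "18-44", 500, table) == pytest.approx(
            expect, rel=1e-12
        )
        assert expect == pytest.approx(1.614e-4, rel=1e-3)

    def test_beyond_five_years_keeps_last_hazard(self):
        table = survival_table()
        h5 = graft_failure_hazard("living", "18-44", 1500, table)
        assert graft_failure_hazard("living", "18-44", 5000, table) == h5

    def test_nonmonotone_input_rejected(self):
        table = survival_table()
        table.loc[0, "s_1y"] = 0.99  # > s_90d = 0.95
        with pytest.raises(ValueError):
            compile_graft_hazards(table)

    def test_survival_round_trip(self):
        """Simulating the derived hazards reproduces the input fractions.

        Piecewise-exponential sampling (the closed-form oracle) of 100,000
        grafts: the Kaplan-Meier-style empirical survival at 90 d / 1 y /
        3 y / 5 y must match the table within binomial Monte-Carlo error.
        """
        table = survival_table()
        h = compile_graft_hazards(table)[codes.DONOR_CODE["deceased"], 1]  # 45-54
        edges = codes.GRAFT_INTERVAL_EDGES.astype(float)
        widths = np.diff(edges)
        cum = np.concatenate([[0.0], np.cumsum(h * widths)])
        rng = np.random.default_rng(7)
        target = -np.log(rng.random(100_000))
        # invert the piecewise-linear cumulative hazard
        seg = np.clip(np.searchsorted(cum, target) - 1, 0, 3)
        t = edges[seg] + (target - cum[seg]) / h[seg]
        for point, frac in zip(edges[1:], (0.95, 0.9, 0.8, 0.7)):
            emp = (t > point).mean()
            half = 2.576 * np.sqrt(frac * (1 - frac) / len(t))
            assert abs(emp - frac) < half


class TestMortalityHazard:
    def test_flat_table_returns_constant(self, bundle_small):
        mt = bundle_small.mortality.copy()
        mt["hazard_per_day"] = 1e-4
        table = MortalityHazardTable(mt)  # multipliers default to 1
        a = agent_on("HD")
        vals = {mortality_hazard(a, table, dt.date(2000, 1, 1) + dt.timedelta(d))
                for d in (1, 100, 400, 2000)}
        assert vals == {1e-4}

    def test_time_band_boundary_is_exact(self, bundle_small):
        table = MortalityHazardTable(bundle_small.mortality)
        a = agent_on("HD")
        start = a.rrt_start_date
        h = lambda d: mortality_hazard(a, table, start + dt.timedelta(days=d))
        assert h(89) == h(1)
        assert h(90) != h(89)  # dialysis band flips on day 90
        assert h(364) == h(90)
        assert h(365) != h(364)

    def test_post_transplant_stages_switch_at_90_and_365(self, bundle_small):
        table = MortalityHazardTable(bundle_small.mortality)
        a = agent_on("Transplant", transplant_date=dt.date(2000, 1, 1), donor_type="living")
        h = lambda d: mortality_hazard(a, table, dt.date(2000, 1, 1) + dt.timedelta(days=d))
        assert h(1) == h(90)          # stage 1 covers <= 90 days
        assert h(91) != h(90)         # stage 2 from day 91
        assert h(365) == h(91)
        assert h(366) != h(365)       # stage 3 beyond one year

    def test_period_multiplier_applies_to_dialysis_only(self, bundle_small):
        mult = np.ones(9)
        mult[4] = 1.5  # 2000-2004
        plain = MortalityHazardTable(bundle_small.mortality)
        scaled = MortalityHazardTable(bundle_small.mortality, mult)
        dial = agent_on("PD")
        tx = agent_on("Transplant", transplant_date=dt.date(2000, 1, 1), donor_type="living")
        day = dt.date(2002, 6, 1)
        assert mortality_hazard(dial, scaled, day) == pytest.approx(
            1.5 * mortality_hazard(dial, plain, day)
        )
        assert mortality_hazard(tx, scaled, day) == mortality_hazard(tx, plain, day)


class TestSwitching:
    def test_zero_hazard_never_switches(self):
        hz = SwitchingHazards(0.0, 0.0)
        rng = np.random.default_rng(0)
        a = agent_on("HD")
        assert all(dialysis_switch_step(a, hz, rng) == "stay" for _ in range(1000))

    def test_direction_is_forced_by_hazards(self):
        hz = SwitchingHazards(h_hd_to_pd=1.0, h_pd_to_hd=0.0)
        rng = np.random.default_rng(1)
        assert dialysis_switch_step(agent_on("HD"), hz, rng) == "switch"
        assert all(
            dialysis_switch_step(agent_on("PD"), hz, rng) == "stay" for _ in range(200)
        )

    def test_switch_count_within_poisson_interval(self):
        hz = SwitchingHazards(h_hd_to_pd=0.001, h_pd_to_hd=0.0)
        rng = np.random.default_rng(2)
        a = agent_on("HD")
        n = sum(dialysis_switch_step(a, hz, rng) == "switch" for _ in range(10_000))
        # 99% interval for a count with mean 10
        assert 2 <= n <= 20
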