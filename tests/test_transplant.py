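"""Transplant pathway: referral rule, durations, eligibility, waiting list."""

import numpy as np
import pytest
from scipy import stats

from dmesrd.transplant import (
    Waitlist,
    WaitlistRates,
    assessment_decision,
    eligibility,
    sample_assessment_duration,
    waitlist_step,
)


class TestAssessmentDecision:
    def test_age_rule_edges(self):
        rng = np.random.default_rng(0)
        assert assessment_decision(50, rng) is True
        assert assessment_decision(65, rng) is True
        assert assessment_decision(80, rng) is False
        assert assessment_decision(76, rng) is False

    def test_66_to_75_accepted_a_quarter_of_the_time(self):
        rng = np.random.default_rng(1)
        n = 10_000
        frac = sum(assessment_decision(70, rng) for _ in range(n)) / n
        half = 2.576 * np.sqrt(0.25 * 0.75 / n)
        assert abs(frac - 0.25) < half


class TestAssessmentDuration:
    def test_erlang_mean(self, bundle_small):
        # shape 4, 30 days per test -> mean 120 days, sd 60
        params = bundle_small.calibrated.replace(
            assessment_appointments=4, assessment_mean_days_per_test=30.0
        )
        rng = np.random.default_rng(2)
        n = 100_000
        draws = np.array(
            [sample_assessment_duration(params, False, rng) for _ in range(n)]
        )
        half = 2.576 * 60.0 / np.sqrt(n)
        assert abs(draws.mean() - 120.0) < half
        assert (draws > 0).all()

    def test_reassessment_bounded_by_180_days(self, bundle_small):
        rng = np.random.default_rng(3)
        draws = np.array(
            [sample_assessment_duration(bundle_small.calibrated, True, rng)
             for _ in range(10_000)]
        )
        assert draws.max() <= 180.0
        assert draws.min() >= 0.0

    def test_reassessment_mode_near_90_days(self, bundle_small):
        rng = np.random.default_rng(4)
        draws = np.array(
            [sample_assessment_duration(bundle_small.calibrated, True, rng)
             for _ in range(100_000)]
        )
        counts, edges = np.histogram(draws, bins=np.arange(-5.0, 195.0, 10.0))
        peak_mid = (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1]) / 2
        assert peak_mid == 90.0


class TestEligibility:
    def test_cutoff_zero_admits_everyone(self):
        assert eligibility(0.0, 0.0) and eligibility(0.73, 0.0)

    def test_cutoff_one_admits_only_the_boundary(self):
        assert not eligibility(0.999999, 1.0)
        assert eligibility(1.0, 1.0)

    def test_uniform_tail_mass(self):
        rng = np.random.default_rng(5)
        coeffs = rng.random(100_000)
        frac = np.mean([eligibility(c, 0.7) for c in coeffs])
        half = 2.576 * np.sqrt(0.3 * 0.7 / len(coeffs))
        assert abs(frac - 0.3) < half


class TestWaitlist:
    def test_duplicate_listing_rejected(self):
        wl = Waitlist()
        wl.add(1, 0.5, "deceased", 0)
        with pytest.raises(ValueError):
            wl.add(1, 0.9, "living", 1)

    def test_zero_rates_change_nothing(self):
        wl = Waitlist()
        wl.add(1, 0.5, "deceased", 0)
        wl.add(2, 0.9, "living", 0)
        rates = WaitlistRates(living=0.0, deceased=0.0, withdrawal=0.0)
        rng = np.random.default_rng(0)
        for day in range(200):
            assert waitlist_step(wl, rates, day, rng) == []
        assert len(wl) == 2

    def test_highest_priority_gets_the_organ(self):
        wl = Waitlist()
        wl.add(1, 0.2, "deceased", 0)
        wl.add(2, 0.9, "deceased", 0)
        rates = WaitlistRates(living=0.0, deceased=50.0, withdrawal=0.0)
        events = waitlist_step(wl, rates, 0, np.random.default_rng(1))
        transplanted = [e[1] for e in events if e[0] == "transplant"]
        assert transplanted[0] == 2  # priority 0.9 first

    def test_priority_ties_break_by_listing_date(self):
        wl = Waitlist()
        wl.add(5, 0.5, "deceased", 10)
        wl.add(3, 0.5, "deceased", 4)
        assert wl.highest_priority("deceased").agent_id == 3

    def test_deceased_count_is_poisson(self):
        """With a never-empty list, transplants over T days ~ Poisson(rT)."""
        rate, horizon = 0.05, 2_000
        rates = WaitlistRates(living=0.0, deceased=rate, withdrawal=0.0)
        rng = np.random.default_rng(2)
        wl = Waitlist()
        next_id = 0
        for i in range(5):
            wl.add(next_id, rng.random(), "deceased", 0)
            next_id += 1
        count = 0
        for day in range(horizon):
            for ev in waitlist_step(wl, rates, day, rng):
                if ev[0] == "transplant":
                    count += 1
                    wl.add(next_id, rng.random(), "deceased", day)  # keep list full
                    next_id += 1
        mean = rate * horizon  # 100
        assert stats.poisson.ppf(0.005, mean) <= count <= stats.poisson.ppf(0.995, mean)

    def test_waiting_time_decreases_with_priority(self):
        """Deceased-pathway wait is (stochastically) shorter at higher priority."""
        rng = np.random.default_rng(3)
        wl = Waitlist()
        prios = rng.random(150)
        for i, p in enumerate(prios):
            wl.add(i, float(p), "deceased", 0)
        rates = WaitlistRates(living=0.0, deceased=0.5, withdrawal=0.0)
        waits = {}
        day = 0
        while len(wl) and day < 5_000:
            for ev in waitlist_step(wl, rates, day, rng):
                waits[ev[1]] = day
            day += 1
        got = sorted(waits)
        rho = stats.spearmanr(prios[got], [waits[i] for i in got]).statistic
        assert rho < -0.9

    def test_living_pathway_bypasses_deceased_queue(self):
        wl = Waitlist()
        wl.add(1, 0.99, "living", 0)
        wl.add(2, 0.01, "deceased", 0)
        rates = WaitlistRates(living=0.0, deceased=100.0, withdrawal=0.0)
        events = waitlist_step(wl, rates, 0, np.random.default_rng(4))
        # the deluge of deceased organs never touches the living-pathway member
        assert ("transplant", 2, "deceased") in events
        assert all(e[1] != 1 for e in events)
        assert 1 in wl.entries

    def test_withdrawal_hazard_empties_list(self):
        wl = Waitlist()
        for i in range(50):
            wl.add(i, i / 50.0, "deceased", 0)
        rates = WaitlistRates(living=0.0, deceased=0.0, withdrawal=0.5)
        rng = np.random.default_rng(5)
        events = []
        for day in range(40):
            events += waitlist_step(wl, rates, day, rng)
        assert len(wl) == 0
        assert all(e[0] == "withdrawal" for e in events)
        assert len(events) == 50
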