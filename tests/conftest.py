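"""Shared fixtures: synthetic bundles and cached scenario runs.

Everything is generated programmatically; simulation fixtures use small
population scales and are session-cached because full-horizon runs cost a
few seconds each.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import dmesrd as dm
from dmesrd.engine import ScenarioConfig, run_realization

MASTER_SEED = 3


@pytest.fixture(scope="session")
def bundle_small():
    """2% scale bundle used for table-level tests."""
    return dm.generate_fixture_bundle(seed=7, scale=0.02)


@pytest.fixture(scope="session")
def bundle_tiny():
    """1% scale bundle used for full-horizon scenario runs."""
    return dm.generate_fixture_bundle(seed=1, scale=0.01)


@pytest.fixture(scope="session")
def baseline_run(bundle_tiny):
    return run_realization(bundle_tiny, ScenarioConfig(master_seed=MASTER_SEED), 0)


@pytest.fixture(scope="session")
def s1_run(bundle_tiny):
    cfg = ScenarioConfig(scenario="no_new_dm_after_2005", master_seed=MASTER_SEED)
    return run_realization(bundle_tiny, cfg, 0)


@pytest.fixture(scope="session")
def s2_run(bundle_tiny):
    cfg = ScenarioConfig(scenario="universal_preemptive_tx", master_seed=MASTER_SEED)
    return run_realization(bundle_tiny, cfg, 0)


def immortal_bundle(base, h_death: float = 0.0, h_esrd: float | None = None):
    """Bundle variant with overridden progression/treatment mortality."""
    cr = base.competing_risks.copy()
    cr["h_death"] = h_death
    if h_esrd is not None:
        cr["h_esrd"] = h_esrd
    mt = base.mortality.copy()
    if h_death == 0.0:
        mt["hazard_per_day"] = 0.0
    return dataclasses.replace(base, competing_risks=cr, mortality=mt)


@pytest.fixture(scope="session")
def calibration_setting():
    """A small, signal-rich setting for calibration experiments.

    ESRD hazards are boosted so the 1% population yields enough transplant
    activity inside a 1980-1995 horizon to identify the pathway parameters.
    """
    b = dm.generate_fixture_bundle(seed=5, scale=0.01)
    cr = b.competing_risks.copy()
    cr["h_esrd"] = cr["h_esrd"] * 15.0
    bundle = dataclasses.replace(b, competing_risks=cr)
    cfg = ScenarioConfig(start_year=1980, end_year=1995, master_seed=0)
    return bundle, cfg
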