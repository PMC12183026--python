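import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("stable", derandomize=True, deadline=None)
hyp_settings.load_profile("stable")

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from ppgr.config import SimulationConfig
from ppgr.simulate import simulate_cohort


def noiseless_config(**over) -> SimulationConfig:
    """Generator settings with every measurement-noise source switched off."""
    base = dict(
        noise_sd=0.0,
        quantization=0.0,
        baseline_wiggle_sd=0.0,
        missing_rate=0.0,
        long_gap_rate=0.0,
        logging_delay_max=0.0,
    )
    base.update(over)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small default-settings cohort shared by read/write and feature tests."""
    return simulate_cohort(SimulationConfig(n_participants=4, n_days=5, seed=7,
                                            standardized_days=(2, 3)))


@pytest.fixture(scope="session")
def tiny_table(tiny_cohort):
    from ppgr.pipeline import cohort_feature_table

    table, counts = cohort_feature_table(tiny_cohort)
    return table, counts


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def random_trace(rng, n=40, interval=15.0, level=5.5, amp=2.0):
    """Gap-free random CGM-like trace for oracle comparisons."""
    t = np.arange(n) * interval
    y = level + amp * np.abs(np.sin(t / 180.0 * rng.uniform(0.5, 2.0))) + rng.normal(0, 0.3, n)
    return t, np.clip(y, 2.5, 25.0)
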