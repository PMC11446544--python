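import numpy as np
import pytest

import cardiorivalry as cr


@pytest.fixture(scope="session")
def regular_train():
    """Perfectly regular 0.8 s rhythm over 60 s."""
    return cr.simulate_rr_series(0.8, 0.0, 60, seed=0)


@pytest.fixture(scope="session")
def noisy_train():
    """Variable sinus rhythm over 120 s."""
    return cr.simulate_rr_series(0.8, 0.05, 120, seed=11)


@pytest.fixture(scope="session")
def clean_ecg(noisy_train):
    record, truth = cr.simulate_ecg(noisy_train, fs=100, noise_sd=0.0, seed=1)
    return record, truth


@pytest.fixture(scope="session")
def noisy_ecg(noisy_train):
    record, truth = cr.simulate_ecg(noisy_train, fs=100, noise_sd=0.05, seed=2)
    return record, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Small rivalry cohort for statistics unit tests."""
    cfg = cr.CohortConfig(n_subjects=12, block_duration=120.0)
    return cr.simulate_rivalry_cohort(cfg, seed=21)
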