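import numpy as np
import pytest

import shortsep as ss


@pytest.fixture(scope="session")
def montage():
    return ss.build_standard_montage()


@pytest.fixture(scope="session")
def small_spec():
    """Short single-subject session for fast unit tests (4 trials/condition)."""
    return ss.SessionSpec(
        n_trials_per_condition=4, baseline_duration=20.0, tail_duration=20.0, n_subjects=1
    )


@pytest.fixture(scope="session")
def truth(montage):
    return ss.default_ground_truth(montage, between_subject_sd=0.0)


@pytest.fixture(scope="session")
def clean_session(small_spec, truth, montage):
    """Noise-free forward-simulated session (deterministic)."""
    raw, schedule = ss.simulate_session(small_spec, truth, ss.ZERO_NOISE, montage, seed=7)
    return raw, schedule


@pytest.fixture(scope="session")
def noisy_session(small_spec, truth, montage):
    raw, schedule = ss.simulate_session(small_spec, truth, ss.NoiseSpec(), montage, seed=7)
    return raw, schedule
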