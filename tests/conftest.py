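import numpy as np
import pytest

from fmriseq.core import AcquisitionParams, default_response_params
from fmriseq.synth import make_sequence_schedule, simulate_probabilities


@pytest.fixture(scope="session")
def response_params():
    return default_response_params()


@pytest.fixture(scope="session")
def acquisition():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def clean_sequence_trials(response_params):
    """Zero-noise simulated sequence trials for one synthetic participant."""
    sched = make_sequence_schedule(seed=3)
    return simulate_probabilities(sched, response_params, noise_sd=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


def by_isi(trials, isi_seconds):
    return [tc for tc in trials if abs(tc.speed.isi_seconds - isi_seconds) < 1e-9]
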