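import numpy as np
import pytest

from nvcouple import RunConfig, SessionConfig, generate_session, run_pipeline


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_config():
    """Three trials per hemisphere, coupling from the second trial onward."""
    return SessionConfig(n_trials_per_hemisphere=3, coupling_onset_trial=2,
                         rng_seed=42)


@pytest.fixture(scope="session")
def small_session(small_config):
    return generate_session(small_config)


@pytest.fixture(scope="session")
def small_session_report(small_session):
    """Pipeline output on the small session (all-pairs mode)."""
    cfg = RunConfig(pairing="all")
    report, ccgs, manifest = run_pipeline(
        cfg, eeg=small_session.eeg, nirs=small_session.nirs,
        schedule=small_session.schedule)
    return report, ccgs, manifest
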