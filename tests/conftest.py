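import warnings

import numpy as np
import pytest

import rapidindex as rx
from rapidindex.synthetic import generate_cohort

#: channel-noise settings for clean (no-loss) synthetic telemetry
CLEAN = dict(
    dropout_rate={"chest_ecg": 0.0, "pulse_ox": 0.0},
    artifact_rate={"chest_ecg": 0.0, "pulse_ox": 0.0},
)


@pytest.fixture(scope="session")
def trained_model():
    """One trained index model shared across tests (36 stable sessions, 12 h)."""
    sessions, _ = generate_cohort(36, 0, seed=2, duration_minutes=720)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return rx.train_rapid(sessions, seed=2)


@pytest.fixture()
def stable_session():
    """A single clean stable session (no dropout/artifact), 400 min."""
    sessions, _ = generate_cohort(1, 0, seed=7, duration_minutes=400, **CLEAN)
    return sessions[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
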