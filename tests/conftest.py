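import numpy as np
import pytest

from synergykit.synthetic import make_ground_truth, synthesize_session

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def truth():
    """Default 3-channel / 2-synergy subject (5% envelope noise)."""
    return make_ground_truth(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def noisy_day1(truth):
    """Day-1 noisy session of the default subject."""
    emg, accel = synthesize_session(truth, day=1, seed=3)
    return emg, accel


@pytest.fixture(scope="session")
def noiseless_truth():
    return make_ground_truth(seed=FIXTURE_SEED, noise_sigma=0.0)


@pytest.fixture(scope="session")
def noiseless_day1(noiseless_truth):
    emg, accel = synthesize_session(noiseless_truth, day=1, seed=3)
    return emg, accel


@pytest.fixture(scope="session")
def small_rank2():
    """Small exactly rank-2 non-negative matrix with rest phases."""
    C = np.array([[1.0, 0.1], [0.7, 0.4], [0.05, 1.0]])
    t = np.linspace(0, 4 * np.pi, 50)
    S = np.vstack(
        [np.clip(np.sin(t), 0, None), np.clip(np.sin(t + np.pi), 0, None)]
    )
    return C @ S
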