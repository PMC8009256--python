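import numpy as np
import pytest

import zapgaze as zg
from zapgaze.validation import events_from_ground_truth


@pytest.fixture(scope="session")
def small_config():
    return zg.SimulationConfig(n_blocks=2, trials_per_block=100, rng_seed=123)


@pytest.fixture(scope="session")
def session(small_config):
    return zg.simulate_session(small_config)


@pytest.fixture(scope="session")
def detected(session):
    return zg.detect_session(
        session.recording, segment_bounds_ms=session.block_bounds_ms
    )


@pytest.fixture(scope="session")
def gt_events(session):
    return events_from_ground_truth(session.ground_truth)


@pytest.fixture(scope="session")
def first_sacc(session, gt_events):
    from zapgaze import metrics

    return metrics.first_saccade_after_onset(session.trials, gt_events)


def flat_recording(n=2000, sd=0.02, seed=0, rate=1250.0, offset=(0.0, 0.0)):
    """Stationary fixation recording with Gaussian position noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) * 1000.0 / rate
    return zg.GazeRecording(
        t,
        offset[0] + rng.normal(0, sd, n),
        offset[1] + rng.normal(0, sd, n),
        rate,
    )
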