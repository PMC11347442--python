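import numpy as np
import pandas as pd
import pytest

import loadlab as ll


def make_random_series(rng, n, zero_fraction=0.1, high=1200.0):
    """Random daily workload series in [0, high] with a share of zero days."""
    w = rng.uniform(0.0, high, size=n)
    w[rng.random(n) < zero_fraction] = 0.0
    return w


@pytest.fixture
def rng():
    return np.random.default_rng(20240813)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic squad: 8 athletes x 211 days."""
    return ll.generate_cohort(ll.SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def default_panel(default_cohort):
    return ll.compute_all_metrics(default_cohort)


@pytest.fixture
def tiny_log():
    """Three days of one athlete, including a 0 A.U. stoppage day."""
    frame = pd.DataFrame({
        "athlete_id": ["a1", "a1", "a1"],
        "day_index": [0, 1, 2],
        "rpe": [7.0, 0.0, 5.0],
        "duration_min": [60.0, 0.0, 90.0],
        "injured": [0, 1, 0],
    })
    return ll.TrainingLog.from_frame(frame)


@pytest.fixture
def tiny_log_path(tiny_log, tmp_path):
    path = tmp_path / "log.csv"
    ll.write_training_log(tiny_log, path)
    return path
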