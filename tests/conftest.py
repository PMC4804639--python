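import numpy as np
import pandas as pd
import pytest

from gazeclass.battery import default_battery
from gazeclass.cohort import default_params, generate_cohort, simulate_fixation_table
from gazeclass.fixtures import load_fixtures
from gazeclass.metrics import compute_fixation_table


@pytest.fixture(scope="session")
def battery():
    return default_battery()


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def default_cohort():
    """Full stream-level default cohort (26 ASD + 35 TD), seed 0."""
    params = default_params(seed=0)
    participants, gaze = generate_cohort(params)
    return params, participants, gaze


@pytest.fixture(scope="session")
def default_fixation_table(default_cohort, battery):
    _, participants, gaze = default_cohort
    return participants, compute_fixation_table(gaze, battery)


@pytest.fixture(scope="session")
def fast_cohort():
    """Count-level default cohort via the vectorised shortcut, seed 0."""
    params = default_params(seed=0)
    participants, table = simulate_fixation_table(params)
    return params, participants, table


def make_stream(battery, coords_by_stimulus):
    """Build a single-participant gaze frame from per-stimulus (x, y, valid) arrays."""
    frames = []
    for spec in battery:
        x, y, valid = coords_by_stimulus[spec.stimulus_id]
        n = spec.n_samples
        assert len(x) == n
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": "P1",
                    "stimulus_id": spec.stimulus_id,
                    "t_ms": np.arange(n) * 20,
                    "x_px": x,
                    "y_px": y,
                    "valid": valid,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
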