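import numpy as np
import pandas as pd
import pytest

from burstlab.synthetic import (
    FieldSpec,
    TelegraphParams,
    TrajectorySpec,
    simulate_population_trajectories,
    simulate_smfish_field,
    simulate_traces,
)

# kinetics matching a bursting locus: mean ON 6.67 min, mean OFF 43.3 min
K_ON_PER_MIN = 1.0 / 43.3
K_OFF_PER_MIN = 1.0 / 6.67


@pytest.fixture(scope="session")
def telegraph_traces():
    """50 traces x 512 frames at dt=100 s, SNR 5 (noise = level/5)."""
    level = 2.0 * 100.0
    params = TelegraphParams(
        k_on=K_ON_PER_MIN, k_off=K_OFF_PER_MIN, noise_sd=level / 5, seed=11
    )
    table, traces = simulate_traces(50, params)
    return table, traces, params


@pytest.fixture(scope="session")
def smfish_field():
    """Default 9-cell field, one 2-RNA transcription site per cell, SNR > 10."""
    return simulate_smfish_field(FieldSpec(seed=3))


@pytest.fixture(scope="session")
def trajectory_table():
    """Sorted-population trajectories at the default study conditions, seed 42."""
    return simulate_population_trajectories(TrajectorySpec(seed=42))


def spot_row(channel, x, y, intensity=100.0, cell_id=1, compartment="nuclear"):
    return {
        "channel": channel,
        "x": x,
        "y": y,
        "intensity": intensity,
        "cell_id": cell_id,
        "compartment": compartment,
    }


@pytest.fixture
def make_spot_table():
    def _make(rows):
        return pd.DataFrame([spot_row(**r) for r in rows])

    return _make
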