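import numpy as np
import pandas as pd
import pytest

from gridglm.config import EnvironmentConfig, SimulationConfig
from gridglm.bold import simulate_bold
from gridglm.trajectory import Trajectory, generate_trajectory


@pytest.fixture(scope="session")
def default_env():
    return EnvironmentConfig()


@pytest.fixture(scope="session")
def default_trajectory(default_env):
    return generate_trajectory(default_env, seed=1)


@pytest.fixture(scope="session")
def noiseless_run(default_trajectory):
    """Perfectly coherent, noise-free planted run (theta* = 23 deg, A = 0.8)."""
    sim = SimulationConfig(
        orientation_concentration=None,
        modulation_amplitude=0.8,
        noise_sd=0.0,
        group_orientation=23.0,
        n_voxels=4,
    )
    return simulate_bold(default_trajectory, sim, seed=7), sim


def make_rest_trajectory(env, x, y):
    """Trajectory consisting of a single stationary rest at (x, y)."""
    events = pd.DataFrame(
        [[0.0, env.run_length, "rest", np.nan, x, y, x, y]],
        columns=["onset", "duration", "trial_type", "direction",
                 "x_start", "y_start", "x_end", "y_end"],
    )
    return Trajectory(events=events, config=env, seed=0)
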