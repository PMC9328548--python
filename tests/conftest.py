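import numpy as np
import pytest

from mtiat import DesignConfig, RaceIAT, simulate_cohort
from mtiat.trajectory import NormalizedBatch, NormalizedTrajectory


@pytest.fixture(scope="session")
def design() -> DesignConfig:
    return DesignConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """Six simulated subjects with the default population."""
    return simulate_cohort(6, seed=123)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    return RaceIAT.from_session_set(small_cohort).fit(n_boot=100, seed=7)


def random_batch(rng: np.random.Generator, n: int, n_steps: int = 101) -> NormalizedBatch:
    """Random smooth-ish 101-step trajectories from (0,0) to a right target."""
    import pandas as pd

    t = np.linspace(0.0, 1.0, n_steps)
    end_x = rng.uniform(0.3, 0.9, size=(n, 1))
    end_y = rng.uniform(0.8, 1.2, size=(n, 1))
    # base straight path plus random smooth wiggle vanishing at the endpoints
    wiggle = np.zeros((n, n_steps))
    for k in range(1, 5):
        wiggle += rng.normal(0, 0.15 / k, size=(n, 1)) * np.sin(np.pi * k * t)[None, :]
    x = end_x * t[None, :] + wiggle
    wiggle2 = np.zeros((n, n_steps))
    for k in range(1, 5):
        wiggle2 += rng.normal(0, 0.15 / k, size=(n, 1)) * np.sin(np.pi * k * t)[None, :]
    y = end_y * t[None, :] + wiggle2
    rts = rng.uniform(500, 1500, n)
    step_times = t[None, :] * rts[:, None]
    keys = pd.DataFrame(
        {"subject": "R", "block": 3, "trial": np.arange(n)}
    )
    return NormalizedBatch(
        keys=keys,
        x=x,
        y=y,
        step_times=step_times,
        initiation_time=rng.uniform(100, 300, n),
        response_time=rts,
    )


def single_trajectory(x, y, rt=1000.0, it=200.0) -> NormalizedTrajectory:
    x = np.asarray(x, float)
    n = len(x)
    return NormalizedTrajectory(
        subject="T",
        block=3,
        trial=0,
        x=x,
        y=np.asarray(y, float),
        step_times=np.linspace(0, rt, n),
        initiation_time=it,
        response_time=rt,
    )
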