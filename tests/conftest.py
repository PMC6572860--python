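from pathlib import Path

import numpy as np
import pytest

from dunewalk.types import ShootMap, StepSample

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def steps20() -> StepSample:
    """The shipped 20-step sample (truncated-Pareto draws, mu=2)."""
    steps = np.loadtxt(DATA_DIR / "steps20.csv", delimiter=",",
                       skiprows=1, usecols=1)
    return StepSample(steps=steps, smin=0.68)


@pytest.fixture
def collinear_map() -> ShootMap:
    return ShootMap(plant_id="collinear", xy=[[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])


def make_pareto_sample(mu: float, n: int, seed: int, smin: float = 0.68,
                       smax: float = 75.33) -> StepSample:
    from dunewalk.walk import sample_step
    rng = np.random.default_rng(seed)
    return StepSample(steps=sample_step(mu, smin, smax, rng.random(n)), smin=smin)
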