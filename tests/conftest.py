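import numpy as np
import pytest

from motorcpd import simulate as sim
from motorcpd.model import IncrementSeries


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def default_params():
    return sim.PhysicalParams()


@pytest.fixture(scope="session")
def two_state_path():
    """One path with a single large velocity change (0.1 -> 0.6 um/s) at
    t = 5 s: 100 + 100 frames."""
    sched = sim.SteppingSchedule((5.0,), (0.1 / 0.008, 0.6 / 0.008))
    return sim.simulate_path(sched, sim.PhysicalParams(), np.random.default_rng(4))


@pytest.fixture(scope="session")
def constant_path():
    """A single-state 0.6 um/s path (no change points)."""
    sched = sim.SteppingSchedule((), (0.6 / 0.008,))
    return sim.simulate_path(sched, sim.PhysicalParams(), np.random.default_rng(3))


def increments(path):
    return IncrementSeries(np.diff(path.obs_positions), path.params.frame_dt)


@pytest.fixture(scope="session")
def two_state_increments(two_state_path):
    return increments(two_state_path)


@pytest.fixture(scope="session")
def constant_increments(constant_path):
    return increments(constant_path)
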