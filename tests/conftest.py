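import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from osmotrace import (
    CellTrajectory,
    ChamberCohort,
    SimulationConfig,
    default_time_grid,
    make_default_panel,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def grid():
    return default_time_grid()  # 91 points, -30..420 min, dt=5


@pytest.fixture
def small_cohort(grid):
    return ChamberCohort(times=grid, initial_cells=20)


@pytest.fixture
def noiseless_config():
    return SimulationConfig().noiseless()


@pytest.fixture
def small_panel():
    return make_default_panel(n_per_archetype=1)


def make_traj(values, cell_id=0, strain="S", times=None, valid=None, condition="0.4M"):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = 5.0 * np.arange(len(values)) - 10.0
    if valid is None:
        valid = np.ones(len(values), dtype=bool)
    return CellTrajectory(cell_id, strain, condition, times, values, valid)
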