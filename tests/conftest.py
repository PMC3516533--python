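import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from symbiosdm.grid_io import ClimateLayerSet, Grid, OccurrenceMap
from symbiosdm.pipeline import DEFAULT_LEARNERS, run_approaches
from symbiosdm.synthetic_data import default_config, generate_scenario

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_layers(n_rows=3, n_cols=4, period="current", **variables) -> ClimateLayerSet:
    """Small layer set; variables default to two deterministic fields."""
    grid = Grid.regular(n_rows, n_cols)
    if not variables:
        n = grid.n_cells
        variables = {
            "t": np.linspace(0.0, 10.0, n),
            "p": np.linspace(100.0, 50.0, n),
        }
    return ClimateLayerSet(grid, period, {k: np.asarray(v, float) for k, v in variables.items()})


def make_occurrence(status, species="sp", n_cols=None) -> OccurrenceMap:
    status = np.asarray(status, dtype=np.int8)
    n = len(status)
    if n_cols is None:
        n_cols = n
    grid = Grid.regular(n // n_cols, n_cols)
    return OccurrenceMap(grid, species, status)


@pytest.fixture(scope="session")
def scenario():
    """Default packaged scenario, seed 1 (host-limited future expansion)."""
    return generate_scenario(default_config(seed=1))


@pytest.fixture(scope="session")
def approach_results(scenario):
    """Host result and the four approach results on the session scenario."""
    host, results = run_approaches(scenario, DEFAULT_LEARNERS, seed=1)
    return host, results
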