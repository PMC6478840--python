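import numpy as np
import pytest

from tmaze.chemotaxis import ChemotaxisParameters
from tmaze.geometry import MazeGeometry, linear_regime_field, log_regime_field
from tmaze.heterogeneity import MazeHeterogeneityModel
from tmaze.population import PopulationHyperparameters, sample_phenotypes


@pytest.fixture(scope="session")
def geom():
    return MazeGeometry()


@pytest.fixture(scope="session")
def linear_field(geom):
    return linear_regime_field(geom)


@pytest.fixture(scope="session")
def log_field(geom):
    return log_regime_field(geom)


@pytest.fixture(scope="session")
def hyper():
    return PopulationHyperparameters()


@pytest.fixture(scope="session")
def params():
    return ChemotaxisParameters()


@pytest.fixture(scope="session")
def model_linear(hyper, geom, linear_field):
    return MazeHeterogeneityModel(hyper, geom, linear_field)


@pytest.fixture(scope="session")
def model_log(hyper, geom, log_field):
    return MazeHeterogeneityModel(hyper, geom, log_field)


@pytest.fixture(scope="session")
def phenotype_sample(hyper):
    """One million phenotype draws shared by the Monte-Carlo cross-checks."""
    return sample_phenotypes(hyper, 1_000_000, seed=20240917 % 2**31)


@pytest.fixture(scope="session")
def small_geom():
    """Compact single-junction device for steady-state transport checks."""
    return MazeGeometry(n_junctions=1, y_v=300.0, horizontal_len=300.0,
                        inlet_len=200.0, inlet_y=300.0,
                        slope_window=(350.0, 550.0))


@pytest.fixture(scope="session")
def pde_states_linear(geom, linear_field, params):
    """Homogeneous linear-regime 2-D run recorded over the observation
    window (coarse grid), shared by transport and acceptance tests."""
    from tmaze.transport import TransportSolver, initial_state

    solver = TransportSolver(geom, field=linear_field, params=params,
                             dx=20.0, dt=2.0)
    times = [m * 60.0 for m in (40, 80, 120, 160)]
    states = solver.run(initial_state(geom, dx=20.0), record_times=times)
    return dict(zip((40, 80, 120, 160), states))


def assert_close(value, expected, rtol, msg=""):
    assert np.isclose(value, expected, rtol=rtol), \
        f"{msg} got {value}, expected {expected} (rtol {rtol})"
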