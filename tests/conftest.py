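import numpy as np
import pytest

from herbiscape.abundance import SpatialAbundanceModel
from herbiscape.simulate import CameraPlan, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated landscape + survey shared across tests."""
    config = SimulationConfig(
        n_x=10,
        n_y=10,
        beta_lambda=(0.3, 0.5, -0.2),
        beta_gamma=(-0.8,),
        phi=2.0,
        sigma=0.2,
        camera_plan=CameraPlan(n_sites=50, effort_range=(15.0, 30.0)),
        seed=7,
    )
    grid, latent, survey, omega = simulate_dataset(config)
    return config, grid, latent, survey


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A quick (but converged enough for smoke purposes) model fit."""
    _, grid, _, survey = small_dataset
    est = SpatialAbundanceModel(
        n_iter=4000,
        n_burn=2000,
        thin=5,
        n_chains=3,
        basis_rank=10,
        random_state=11,
    )
    return est.fit(survey, grid)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
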