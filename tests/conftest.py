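import numpy as np
import pytest

from raceconf import EvidenceModelParams, ExperimentDesign
from raceconf import pipeline


@pytest.fixture(scope="session")
def default_params():
    return EvidenceModelParams.default(seed=7)


@pytest.fixture(scope="session")
def small_design():
    return ExperimentDesign(n_reps=3)


@pytest.fixture(scope="session")
def small_pool(default_params, small_design):
    """Desk-sized pooled model run shared by the unit tests."""
    return pipeline.simulate_model_pool(
        default_params, design=small_design, n_instances=8, pool_reps=3,
        cal_per_class=60, seed=11)


@pytest.fixture(scope="session")
def posterior_model(small_pool):
    return small_pool.posterior_model


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
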