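import numpy as np
import pytest

import socarb
from socarb.inversion import OptimizerConfig
from socarb.params import group_mean_perceptual, group_mean_response


@pytest.fixture(scope="session")
def default_schedule():
    return socarb.generate_schedule(socarb.GeneratorConfig())


@pytest.fixture(scope="session")
def group_params():
    return group_mean_perceptual(), group_mean_response()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fast_optimizer():
    """Reduced multi-start budget for unit tests."""
    return OptimizerConfig(n_starts=3, maxiter=300, seed=7)
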