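import numpy as np
import pytest

from mmn_dcm.model_space import build_demo_network, default_priors
from mmn_dcm.synthetic import make_leadfield, make_cohort


@pytest.fixture(scope="session")
def demo_net():
    return build_demo_network()


@pytest.fixture(scope="session")
def demo_priors(demo_net):
    return default_priors(demo_net)


@pytest.fixture(scope="session")
def demo_leadfield(demo_net):
    return make_leadfield(32, demo_net, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(demo_net):
    return make_cohort(2, 2, {}, seed=5, network=demo_net)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
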