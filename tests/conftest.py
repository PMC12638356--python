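import numpy as np
import pytest

from grasemwi.epg import EchoTrainSpec, build_t2_grid
from grasemwi.phantom import default_echo_train, make_brain_like_phantom


@pytest.fixture(scope="session")
def grid40():
    """Conventional 40-point logarithmic T2 grid on [15, 2000] ms."""
    return build_t2_grid(40, 15.0, 2000.0)


@pytest.fixture(scope="session")
def mse_spec():
    """32-echo spin-echo train, 10 ms spacing, no gradient echoes."""
    return EchoTrainSpec(n_se=32, esp=10.0, refocus_fa=180.0)


@pytest.fixture(scope="session")
def grase_spec():
    """32-spin-echo GRASE train with two gradient echoes at +/-2.5 ms."""
    return default_echo_train(n_ge=2)


@pytest.fixture(scope="session")
def brain48():
    """Small brain-like phantom shared by the slower pipeline tests."""
    return make_brain_like_phantom((48, 48), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
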