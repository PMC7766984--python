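import numpy as np
import pytest

from medfuse import network


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_params():
    """Small random (untrained) network for plumbing tests."""
    return network.init_params(seed=0, widths={"c1": 4, "cidn": 4, "d1": 4, "d2": 3})
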