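import numpy as np
import pytest
from hypothesis import settings

from cmqleaf import published_cmq_network

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def net():
    """The published 2-3-3 quasi-color network."""
    return published_cmq_network()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
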