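import numpy as np
import pytest

from termstarr import synthio


@pytest.fixture(scope="session")
def small_library():
    """60 motif-planted synthetic terminators shared across tests."""
    return synthio.make_library(60, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_library):
    return synthio.make_ground_truth(small_library, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
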