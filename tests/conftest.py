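import numpy as np
import pytest

from polyprot import synthetic


@pytest.fixture
def helix20():
    return synthetic.make_ideal_helix(20)


@pytest.fixture
def sphere_pair_touching():
    # centre distance below 2*(r+probe): caps overlap
    return synthetic.make_sphere_pair(1.7, 3.1)


@pytest.fixture
def two_domain():
    return synthetic.make_two_domain(4.0, seed=11)


@pytest.fixture
def metal_site():
    return synthetic.make_metal_site("CA", distance=2.4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
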