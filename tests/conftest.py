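import numpy as np
import pytest

from hygroelast import Box, make_toy_polymer, make_water_box


@pytest.fixture(scope="session")
def water_box20():
    """20 rigid waters in a 12 Å periodic cube (fixed seed)."""
    return make_water_box(20, Box((12.0, 12.0, 12.0)), seed=11, min_dist=2.0)


@pytest.fixture(scope="session")
def lignin3():
    """Three lignin-like units in a roomy box."""
    return make_toy_polymer("lignin_like", 3, seed=4, box=Box((30.0, 15.0, 15.0)))


@pytest.fixture(scope="session")
def xylan3():
    """Three xylan-like units in a roomy box."""
    return make_toy_polymer("xylan_like", 3, seed=4, box=Box((25.0, 12.0, 12.0)))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
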