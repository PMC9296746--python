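import numpy as np
import pytest

from spectsynth.geometry import cylinder_support, get_preset


@pytest.fixture(scope="session")
def desk_grid():
    return get_preset("desk")


@pytest.fixture(scope="session")
def desk_support(desk_grid):
    return cylinder_support(desk_grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
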