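import numpy as np
import pandas as pd
import pytest

from edudist.hierarchy import Hierarchy
from edudist.synthetic import make_world


@pytest.fixture(scope="session")
def small_world():
    """3 super-regions x 2 regions x 2 countries, 1970-2018."""
    return make_world(3, 2, 2, (1970, 2018), seed=1234)


@pytest.fixture(scope="session")
def hierarchy(small_world):
    return small_world[0]


@pytest.fixture(scope="session")
def truth(small_world):
    return small_world[1]


@pytest.fixture
def rng():
    return np.random.default_rng(99)


@pytest.fixture
def flat_hierarchy():
    """Tiny hand-built hierarchy for unit tests."""
    return Hierarchy(pd.DataFrame({
        "location_id": ["A", "B", "C", "D"],
        "region": ["R1", "R1", "R2", "R3"],
        "super_region": ["S1", "S1", "S1", "S2"],
    }))


def random_distribution(rng, n=1):
    """Random simplex points over 19 bins."""
    x = rng.gamma(1.0, 1.0, size=(n, 19))
    x = x / x.sum(axis=1, keepdims=True)
    return x[0] if n == 1 else x
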