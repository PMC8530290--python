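import numpy as np
import pytest

from spheredemons.mesh import make_icosphere


@pytest.fixture(scope="session")
def ico2():
    """162-vertex icosphere shared across tests (read-only)."""
    return make_icosphere(2)


@pytest.fixture(scope="session")
def ico3():
    return make_icosphere(3)


@pytest.fixture(scope="session")
def ico4():
    return make_icosphere(4)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_unit_vectors(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)
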