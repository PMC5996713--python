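import numpy as np
import pytest

from effconn.graphs import enumerate_dags


@pytest.fixture(scope="session")
def catalog():
    return enumerate_dags(3)


@pytest.fixture(scope="session")
def univariate_config(catalog):
    """The X->Y configuration (single edge (0, 1))."""
    A = np.zeros((3, 3), dtype=int)
    A[0, 1] = 1
    return catalog[catalog.index_of(A)]


@pytest.fixture(scope="session")
def chain_config(catalog):
    """The X->Y->Z configuration."""
    A = np.zeros((3, 3), dtype=int)
    A[0, 1] = 1
    A[1, 2] = 1
    return catalog[catalog.index_of(A)]


@pytest.fixture(scope="session")
def full_dag_config(catalog):
    """The full order X->Y, X->Z, Y->Z."""
    A = np.zeros((3, 3), dtype=int)
    A[0, 1] = A[0, 2] = A[1, 2] = 1
    return catalog[catalog.index_of(A)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
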