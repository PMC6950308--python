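import numpy as np
import pytest

from kunitzchar.datasets import (
    ATPI_I_CHAIN,
    ATPI_I_PEPTIDES,
    ATPI_II_CHAIN,
    ATPI_II_PEPTIDES,
)


@pytest.fixture(scope="session")
def atpi1_chain() -> str:
    return ATPI_I_CHAIN


@pytest.fixture(scope="session")
def atpi2_chain() -> str:
    return ATPI_II_CHAIN


@pytest.fixture(scope="session")
def atpi1_peptides():
    return ATPI_I_PEPTIDES


@pytest.fixture(scope="session")
def atpi2_peptides():
    return ATPI_II_PEPTIDES


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20190701)
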