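import numpy as np
import pytest

from ionmut import io as ionmut_io


@pytest.fixture(scope="session")
def junction_pairs():
    """Packaged fully printed wild-type/mutant junction pairs (11 rows)."""
    return ionmut_io.load_junction_pairs()


@pytest.fixture(scope="session")
def partial_junctions():
    """Packaged partially printed deletion junctions (4 rows)."""
    return ionmut_io.load_partial_junctions()


@pytest.fixture(scope="session")
def catalog():
    """Packaged 23-row mutation catalog (22 identified + 1 NM)."""
    return ionmut_io.load_reference_catalog()


@pytest.fixture(scope="session")
def cohorts():
    """Packaged screening cohorts (three irradiation conditions)."""
    return ionmut_io.load_cohorts()


@pytest.fixture
def rng():
    return np.random.default_rng(20110)
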