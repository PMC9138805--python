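import numpy as np
import pytest

from lipidmrm.library_config import default_library

SMALL_COUNTS = {
    "SM": 4, "CE": 4, "Cer": 5, "TAG": 20, "DAG": 6, "MAG": 3,
    "LPC": 4, "PC": 8, "LPE": 3, "PE": 10, "LPG": 2, "PG": 6,
    "LPI": 2, "PI": 6, "LPS": 2, "PS": 6, "PA": 6,
}


@pytest.fixture(scope="session")
def full_library():
    """The complete default panel (1218 entries + 12 standards)."""
    return default_library()


@pytest.fixture(scope="session")
def small_library():
    """A down-scaled panel for fast simulation tests."""
    return default_library(SMALL_COUNTS)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
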