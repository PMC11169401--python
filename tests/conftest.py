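import numpy as np
import pytest

from batdisturb.synthetic import SyntheticConfig, generate_dataset
from batdisturb.table1 import table1_fixture


@pytest.fixture(scope="session")
def fixture():
    """The packaged survey table with response annotations."""
    return table1_fixture()


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic bundle shared by I/O and pipeline tests."""
    config = SyntheticConfig(seed=11, n_caves=3, seasons=("2014/2015",))
    return generate_dataset(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240612)
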