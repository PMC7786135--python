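import warnings

import numpy as np
import pytest

import metacov as mc

# the density sweep legitimately runs out of positive weights at high
# densities on small-sample networks; tests assert on it explicitly where
# relevant and ignore it elsewhere
warnings.filterwarnings(
    "ignore", message="fewer positive weights than requested edges"
)


@pytest.fixture(scope="session")
def default_table():
    return mc.make_region_table()


@pytest.fixture(scope="session")
def small_table():
    """Six-node table for fast numerical tests."""
    return mc.make_region_table(4, 1, 1, seed_name="insula")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
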