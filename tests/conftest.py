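import numpy as np
import pytest

from inhibikit import synthdata, ufscreen


@pytest.fixture(scope="session")
def reference_table():
    return ufscreen.load_reference_table()


@pytest.fixture(scope="session")
def reference_tables():
    return ufscreen.reference_peak_tables()


@pytest.fixture(scope="session")
def competitive_grid():
    """Noiseless competitive-inhibition velocities at the reference parameters."""
    return synthdata.gen_velocity_data(
        180.0, 1.0, 5.1, [45, 90, 180, 360, 720], [0, 2.5, 5, 10], "competitive"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
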