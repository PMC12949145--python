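import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from uteromap.io import ElectrodeGrid


@pytest.fixture(scope="session")
def grid() -> ElectrodeGrid:
    """The default 16x4 taped-array grid at 0.95 mm pitch."""
    return ElectrodeGrid()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
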