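import numpy as np
import pandas as pd
import pytest

from clinekit.synthetic_data import SimConfig, simulate_transect


@pytest.fixture(scope="session")
def transect_x() -> np.ndarray:
    """12 evenly spaced sites over a 1,400 km transect."""
    return np.linspace(0.0, 1400.0, 12)


@pytest.fixture(scope="session")
def geometry() -> pd.DataFrame:
    """Default 12-population synthetic transect geometry."""
    return simulate_transect(SimConfig(seed=0, position_jitter=0.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
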