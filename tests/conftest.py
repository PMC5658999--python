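import numpy as np
import pandas as pd
import pytest

from dimcoef import GridConfig, run_grid


@pytest.fixture(scope="session")
def full_grid() -> pd.DataFrame:
    """The complete 5 x 20 x 20 study grid (2000 scenarios), PA with 20
    replicates, one master seed.  Shared by the acceptance checks."""
    config = GridConfig(master_seed=0, pa_replicates=20)
    return run_grid(config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_matrix() -> np.ndarray:
    """4 persons x 3 items with known alpha (hand-computed in tests)."""
    return np.array(
        [
            [0, 1, 2],
            [1, 2, 2],
            [2, 2, 3],
            [4, 3, 4],
        ],
        dtype=float,
    )
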