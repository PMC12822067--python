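import numpy as np
import pandas as pd
import pytest

from mdrsmap.benchmarks import jacobian_recovery, null_control
from mdrsmap.simulate import CommunityParams, random_interaction_matrix, simulate_community


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """A 5-taxon noisy community used by several unit tests."""
    rng = np.random.default_rng(7)
    A = random_interaction_matrix(5, connectance=0.2, rng=rng)
    params = CommunityParams(n_taxa=5, A=A, sigma_proc=0.05, seed=7)
    return simulate_community(params, 120, burn_in=50)


@pytest.fixture(scope="session")
def recovery_result():
    """The 5-seed, 12-taxon, 400-bin Jacobian-recovery benchmark (shared)."""
    return jacobian_recovery(seed=0, n_seeds=5)


@pytest.fixture(scope="session")
def null_result():
    """Zero-interaction community inference + classification (shared)."""
    return null_control(seed=1)


@pytest.fixture
def toy_table():
    """5 taxa x 10 dated samples with hand-chosen abundances."""
    dates = pd.date_range("2020-01-01", periods=10, freq="3D")
    vals = np.array(
        [
            [0.002] * 10,                      # always present, above detection
            [0.02, 0.03] * 5,                  # abundant, always present
            [0.0005] * 10,                     # present but below detection
            [0.05, 0, 0, 0, 0.04, 0, 0, 0, 0.06, 0],  # rare occupancy 0.3
            [0.01, 0.01, 0.01, 0.01, 0.01, 0, 0, 0, 0, 0],  # occupancy 0.5
        ]
    )
    return pd.DataFrame(vals, index=[f"t{i}" for i in range(5)], columns=dates)
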