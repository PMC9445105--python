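import numpy as np
import pytest

from l2psync.data import DatasetSpec, build_balanced_dataset
from l2psync.graphs import NwsParams


@pytest.fixture(scope="session")
def fca15_small():
    """Small balanced FCA dataset on 15-node NWS graphs (paper-style conditions)."""
    spec = DatasetSpec(
        "fca", NwsParams(15, 2, 0.65, 1), r=25, T=70, quota=60, kappa=5, seed=11
    )
    return build_balanced_dataset(spec)


@pytest.fixture(scope="session")
def ghm30_small():
    spec = DatasetSpec(
        "ghm", NwsParams(30, 2, 0.65, 1), r=10, T=70, quota=50, kappa=5, seed=12
    )
    return build_balanced_dataset(spec)


@pytest.fixture(scope="session")
def km15_small():
    """Kuramoto dataset with a short horizon: cheap fixture for IO/feature tests."""
    spec = DatasetSpec(
        "km", NwsParams(15, 2, 0.85, 1), r=6, T=200, quota=40, kappa=None, seed=13
    )
    return build_balanced_dataset(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
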