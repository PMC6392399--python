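import numpy as np
import pytest

from ducksel.catalog import default_catalog
from ducksel.synthetic import SimConfig, generate_landscape


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def small_bundle():
    """Small synthetic landscape shared across tests (deterministic)."""
    cfg = SimConfig(seed=11, n_rows=250, n_cols=250, radius_km=3.0, n_animals=6)
    return cfg, generate_landscape(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
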