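import numpy as np
import pytest

from socquant.model import ModelSpec, SYNTHETIC_STUDY_TRAINING, split_data, train
from socquant.synthetic import SyntheticConfig, generate_grid, generate_sites


@pytest.fixture(scope="session")
def site_config():
    return SyntheticConfig(n_sites=8000, seed=11)


@pytest.fixture(scope="session")
def sites(site_config):
    return generate_sites(site_config)


@pytest.fixture(scope="session")
def split(sites):
    pool_idx, test_idx, resamples = split_data(sites, 0.05, seed=11)
    return pool_idx, test_idx, resamples


@pytest.fixture(scope="session")
def trained_model(sites, split):
    """Pooled quantile network trained once per session on the synthetic pool."""
    pool_idx, _, _ = split
    return train(sites.iloc[pool_idx], ModelSpec(), SYNTHETIC_STUDY_TRAINING)


@pytest.fixture(scope="session")
def demo_grid(site_config):
    return generate_grid(12, 10, site_config, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
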