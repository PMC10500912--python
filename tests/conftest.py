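import numpy as np
import pytest

from quanvnet import data_synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small, easily separable synthetic set shared across tests."""
    spec = data_synth.SyntheticSpec(n_per_class=12, m=8, noise_sd=0.05, seed=7)
    return data_synth.generate_dataset(spec)
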