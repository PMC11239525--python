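import numpy as np
import pytest

from epistate.synthetic import simulate_dataset


@pytest.fixture(scope="session")
def dataset():
    """Default-scale synthetic dataset shared by recovery tests."""
    return simulate_dataset(seed=7)


@pytest.fixture(scope="session")
def domain_results(dataset):
    """Bivalent/switching calls on the default dataset (shared: expensive)."""
    from epistate.pipeline import domain_calls

    return domain_calls(dataset, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
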