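import numpy as np
import pytest

from palmclim.synthetic import SyntheticConfig, generate_dataset
from palmclim.variability import build_record


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic dataset shared by read-only tests."""
    return generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def record(dataset):
    return build_record("synthetic", dataset.yields)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
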