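import numpy as np
import pytest

from spermhist.synthetic_data import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One shared small dataset; tests must not mutate it."""
    return generate_dataset(GeneratorConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
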