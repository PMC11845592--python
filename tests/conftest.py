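import numpy as np
import pytest

from kneetwin.phantom import PhantomConfig


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """A small, fast phantom population used across modules."""
    return PhantomConfig(n_subjects=8, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
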