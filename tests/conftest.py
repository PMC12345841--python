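import numpy as np
import pytest

from focalaug import PhantomConfig, generate_dataset, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_phantom():
    return generate_phantom(
        PhantomConfig(image_size=96, seed=11), np.random.default_rng(11), "ph0"
    )


@pytest.fixture(scope="session")
def small_dataset():
    """20 phantoms at 96 px, split 14/4/2."""
    return generate_dataset(20, PhantomConfig(image_size=96, seed=5))
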