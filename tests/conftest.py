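import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def constant50():
    return np.full((256, 256), 50.0)


@pytest.fixture(scope="session")
def small_dataset():
    """Small 10-class noise dataset shared by classifier unit tests."""
    from psidenoise.noise import make_noise_dataset

    return make_noise_dataset(per_class_count=20, size=64, seed=7)
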