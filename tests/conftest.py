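import numpy as np
import pytest
from hypothesis import settings

from orivec import build_vocabulary, make_toy_fixture

# reproducible property tests: derive examples from the test name alone
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def toy_dataset():
    return make_toy_fixture()


@pytest.fixture(scope="session")
def cont_vocab():
    return build_vocabulary("continuous")


@pytest.fixture(scope="session")
def skip_vocab():
    return build_vocabulary("skip")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
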