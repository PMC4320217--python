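import numpy as np
import pytest

from antbridge.environment import build_default_environment


@pytest.fixture(scope="session")
def default_env():
    return build_default_environment()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
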