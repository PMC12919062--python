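import numpy as np
import pytest
from hypothesis import settings

from pulsedecon.templates import default_priors

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def priors():
    return default_priors()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
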