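import numpy as np
import pytest
from hypothesis import settings

from anticiprf import design, glm

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def apertures128():
    return design.build_bar_apertures(resolution=128)


@pytest.fixture(scope="session")
def apertures64():
    return design.build_bar_apertures(resolution=64)


@pytest.fixture(scope="session")
def hrf():
    return glm.double_gamma_hrf()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
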