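import numpy as np
import pytest

from slnf.fixtures import profile_geometry
from slnf.system_matrix import build_system_matrix


@pytest.fixture(scope="session")
def tiny_model():
    return profile_geometry("tiny")


@pytest.fixture(scope="session")
def tiny_matrix(tiny_model):
    return build_system_matrix(tiny_model)


@pytest.fixture(scope="session")
def default_model():
    return profile_geometry("default")


@pytest.fixture(scope="session")
def default_matrix(default_model):
    return build_system_matrix(default_model)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
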