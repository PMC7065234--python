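import numpy as np
import pytest

from lipidex import fixtures as fixture_lib


@pytest.fixture(scope="session")
def psh_fixture():
    return fixture_lib.load_fixture("psh_titration")


@pytest.fixture(scope="session")
def murj_fixture():
    return fixture_lib.load_fixture("murj_lipid2")


@pytest.fixture(scope="session")
def leut_fixture():
    return fixture_lib.load_fixture("leut_cdl_sites")


@pytest.fixture(scope="session")
def access_fixture():
    return fixture_lib.load_fixture("murj_access")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
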