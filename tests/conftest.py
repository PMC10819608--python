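import numpy as np
import pytest

import hemescore as hs


@pytest.fixture(scope="session")
def resting():
    return hs.fixture("resting_state_h2o")


@pytest.fixture(scope="session")
def obs_gz(resting):
    return resting.observers[0]


@pytest.fixture(scope="session")
def g_resting(resting):
    return resting.system.g_vector


def nucleus(fix, label):
    return next(n for n in fix.system.nuclei if n.label == label)


@pytest.fixture(scope="session")
def h1(resting):
    return nucleus(resting, "H1")


@pytest.fixture(scope="session")
def n1(resting):
    return nucleus(resting, "N1a")


@pytest.fixture(scope="session")
def single_proton_system(resting, h1):
    return hs.SpinSystem(resting.system.g_principal, (h1,))
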