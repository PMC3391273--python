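import numpy as np
import pytest

from enmfold import synthetic_data as sd


@pytest.fixture(scope="session")
def path_chain_10():
    return sd.make_path_chain(10)


@pytest.fixture(scope="session")
def globule_50():
    return sd.make_globule(50, seed=3)


@pytest.fixture(scope="session")
def dumbbell():
    return sd.make_dumbbell(15, 2, seed=0)


@pytest.fixture(scope="session")
def helix_fa_12():
    return sd.make_helix(12, full_atom=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
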