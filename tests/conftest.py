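import numpy as np
import pytest

from conregid import load_matrix


@pytest.fixture(scope="session")
def b62():
    return load_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def b50():
    return load_matrix("BLOSUM50")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_protein(rng, length):
    from conregid.seqdata import AMINO_ACIDS

    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))
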