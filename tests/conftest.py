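import numpy as np
import pytest

from mitospectra.reference import CircularGenome, rcrs, rcrs_annotation


@pytest.fixture(scope="session")
def genome():
    return rcrs()


@pytest.fixture(scope="session")
def annot():
    return rcrs_annotation()


@pytest.fixture(scope="session")
def small_genome():
    """A 2 kb random circular genome (fixed seed)."""
    rng = np.random.default_rng(12345)
    seq = "".join(rng.choice(list("ACGT"), 2000))
    return CircularGenome("small", seq)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
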