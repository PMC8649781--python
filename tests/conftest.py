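import numpy as np
import pytest
from hypothesis import settings

from tnends.io import Params

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def params():
    return Params()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n, gc=0.5):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


@pytest.fixture
def dna_factory():
    return random_dna
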