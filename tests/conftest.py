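import numpy as np
import pytest

from vhhseq import default_reference


@pytest.fixture(scope="session")
def ref():
    return default_reference()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, length):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
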