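import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_dna(rng, n, gc=0.68):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def random_protein(rng, n, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(rng.choice(list(alphabet), size=n))
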