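import numpy as np
import pytest
from hypothesis import settings

from cbei.seqcore import load_genetic_code

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def standard_code():
    return load_genetic_code(1)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_seq(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
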