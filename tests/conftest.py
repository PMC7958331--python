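import numpy as np
import pytest

from regscan.motifscan import BUILTIN_CATALOG


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def catalog_by_name():
    return {m.name: m for m in BUILTIN_CATALOG}


def random_dna(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))
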