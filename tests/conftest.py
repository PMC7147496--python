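import numpy as np
import pytest
from hypothesis import settings

from estmir.io import ReferenceMiRNA, SequenceRecord

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")

_BASES = list("ACGT")


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_refs(rng):
    return [
        ReferenceMiRNA(id=f"syn-miR{300 + i}a-5p", seq=random_seq(rng, 19 + i % 3))
        for i in range(6)
    ]


@pytest.fixture
def small_ests(rng):
    return [
        SequenceRecord(id=f"e{i}", seq=random_seq(rng, 250)) for i in range(8)
    ]
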