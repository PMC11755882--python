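import random

import pytest

from xmeralign.index import build_index
from xmeralign.penalty import PRESETS


@pytest.fixture(scope="session")
def setting1():
    return PRESETS["setting1"]


@pytest.fixture(scope="session")
def small_genome():
    """A 20 kb random genome shared across alignment tests."""
    rng = random.Random(20240)
    return "".join(rng.choices("ACGT", k=20000))


@pytest.fixture(scope="session")
def small_index(small_genome):
    return build_index([("chr1", small_genome)])
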