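import numpy as np
import pytest

from gdenoise import ReferenceGenome


def random_genome(seed: int, length: int, name: str = "c1") -> ReferenceGenome:
    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
    return ReferenceGenome([(name, seq)])


def random_seq(seed: int, length: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


@pytest.fixture
def small_genome() -> ReferenceGenome:
    return random_genome(17, 2000)
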