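import numpy as np
import pytest

from seqcomplexity import Genome


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_genome() -> Genome:
    return Genome(id="tiny", sequence="ACA", original_length=3, removed_bases=0)


def make_genome(sequence: str, gid: str = "g") -> Genome:
    return Genome(
        id=gid, sequence=sequence, original_length=len(sequence), removed_bases=0
    )
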