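import numpy as np
import pytest

from offscan.genome_io import SequenceRecord
from offscan.simulate import random_genome


@pytest.fixture(scope="session")
def small_genome() -> SequenceRecord:
    """50-kb uniform random genome shared across tests."""
    return random_genome(50_000, seed=2024, record_id="g50k")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
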