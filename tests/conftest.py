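import numpy as np
import pytest

from osseq.genome import Genome
from osseq.simulate import simulate_genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genome():
    genome, _ = simulate_genome(800, 42)
    return genome


@pytest.fixture
def clean_genome_5k():
    genome, _ = simulate_genome(5000, 7)
    return genome
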