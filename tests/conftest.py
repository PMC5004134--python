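import numpy as np
import pytest

from hybasm.anchor_index import ContigSet, build_unique_kmer_index
from hybasm.synthetic_data import standard_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_dataset():
    """A 40 kb, 20x, 15%-error simulation shared across tests."""
    return standard_dataset(7, genome_length=40_000, coverage=20, gap_rate=2.0)


@pytest.fixture(scope="session")
def small_index(small_dataset):
    return build_unique_kmer_index(ContigSet(small_dataset.contigs), 17)
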