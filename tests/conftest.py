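import numpy as np
import pytest

from lnccarto.encoding import KmerEmbeddingTable
from lnccarto.synthetic import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """A fast, small but still separable synthetic configuration."""
    return SynthConfig(
        n_coding=12,
        n_noncoding=12,
        length_range_coding=(900, 1000),
        length_range_noncoding=(400, 700),
        orf_length_range=(300, 600),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def tiny_table() -> KmerEmbeddingTable:
    return KmerEmbeddingTable.random(k=3, dim=8, seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
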