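import numpy as np
import pytest

from gbskaryo.genome import Chromosome, GenomeModel, make_bins


@pytest.fixture
def tiny_genome():
    """Two wheat chromosomes and one rye chromosome, Mb-scale."""
    return GenomeModel(
        (
            Chromosome("1A", "A", 10_000_000, 4_500_000),
            Chromosome("2B", "B", 8_000_000, 3_200_000),
            Chromosome("1R", "R", 6_000_000, 2_400_000),
        )
    )


@pytest.fixture
def tiny_grid(tiny_genome):
    return make_bins(tiny_genome, 1_000_000)


@pytest.fixture
def rng():
    return np.random.default_rng(20240514)
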