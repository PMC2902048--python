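import numpy as np
import pytest

from shrinkqtl import GeneticMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_map():
    """Ten markers at 10 cM spacing on one chromosome."""
    pos = np.arange(0.0, 100.0, 10.0)
    return GeneticMap([f"m{i}" for i in range(10)], ["1"] * 10, pos)


@pytest.fixture
def two_chrom_map():
    """Two chromosomes, four markers each, uneven spacing."""
    pos = [0.0, 7.5, 20.0, 33.0, 0.0, 12.0, 12.0, 30.0]
    chroms = ["1"] * 4 + ["2"] * 4
    return GeneticMap([f"m{i}" for i in range(8)], chroms, pos)
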