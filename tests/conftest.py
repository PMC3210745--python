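import numpy as np
import pytest

from apobreak.intervals import GenomeIndex, GenomicInterval
from apobreak.simulate import SimConfig


@pytest.fixture
def genome():
    return GenomeIndex({"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture
def small_sim():
    """Fast simulation settings for structural checks."""
    return SimConfig(
        n_chroms=2,
        chrom_length=200_000,
        n_genes=8,
        n_fragments=4_000,
        seed=123,
    )


def random_intervals(rng, n, genome, max_width=5_000):
    """Uniform random valid intervals over a genome index."""
    chroms = list(genome)
    out = []
    for _ in range(n):
        c = chroms[rng.integers(len(chroms))]
        w = int(rng.integers(1, max_width))
        s = int(rng.integers(0, genome[c] - w))
        out.append(GenomicInterval(c, s, s + w))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20231)
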