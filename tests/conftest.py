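import numpy as np
import pytest

from nadscan.genome_model import ChromosomeMap, GenomicInterval
from nadscan.synthetic_data import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_map():
    return ChromosomeMap([("chr1", 1_000_000), ("chr2", 500_000)])


@pytest.fixture
def tiny_sim_config():
    """A fast simulation: one 12 Mb chromosome, two planted domains."""
    return SimulationConfig(
        chrom_lengths=[12_000_000],
        n_planted=2,
        size_log_range=(500_000, 1_000_000),
        min_gap_bp=500_000,
        n_reads=15_000,
        seed=7,
    )


def random_intervals(rng, n, chrom_len, chrom="chr1", max_size=None):
    """Helper shared across test modules."""
    max_size = max_size or max(chrom_len // 10, 2)
    starts = rng.integers(0, chrom_len - 1, size=n)
    sizes = rng.integers(1, max_size, size=n)
    return [
        GenomicInterval(chrom, int(s), int(min(s + z, chrom_len)))
        for s, z in zip(starts, sizes)
        if min(s + z, chrom_len) > s
    ]
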