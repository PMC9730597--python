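import numpy as np
import pandas as pd
import pytest

from regevo import Genome, RegionSet


@pytest.fixture
def genome():
    return Genome("toy", {"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture
def small_genome():
    return Genome("tiny", {"chr1": 60_000})


def make_regions(rows, genome=None):
    """rows: list of (chrom, start, end) tuples."""
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]), genome)


@pytest.fixture
def random_regions(genome):
    def _make(n, seed=0, min_len=50, max_len=5000):
        rng = np.random.default_rng(seed)
        chroms = np.where(rng.random(n) < 0.7, "chr1", "chr2")
        lens = rng.integers(min_len, max_len, size=n)
        caps = np.where(chroms == "chr1", 1_000_000, 500_000) - lens
        starts = (rng.random(n) * caps).astype(np.int64)
        return RegionSet(
            pd.DataFrame({"chrom": chroms, "start": starts, "end": starts + lens}),
            genome,
        )

    return _make
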