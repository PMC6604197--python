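import numpy as np
import pytest

from betshift.genome import GeneModel, GenomeAnnotation, Interval


@pytest.fixture
def small_annotation() -> GenomeAnnotation:
    """Handcrafted annotation: three genes on one 100 kb chromosome."""
    return GenomeAnnotation(
        chrom_sizes={"chr1": 100_000},
        genes=[
            GeneModel("GA", "TA", "chr1", "+", 5_000, 12_000),
            GeneModel("GB", "TB", "chr1", "-", 30_000, 24_000),
            GeneModel("GC", "TC", "chr1", "+", 60_000, 66_000),
        ],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_intervals(rng, n, chrom="chr1", max_pos=100_000, min_len=100, max_len=2000):
    starts = rng.integers(0, max_pos - max_len, n)
    lengths = rng.integers(min_len, max_len, n)
    return [Interval(chrom, int(s), int(s + l)) for s, l in zip(starts, lengths)]
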