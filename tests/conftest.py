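import numpy as np
import pytest

from tadvar.genome_intervals import GenomeLayout, GenomicInterval, RegionSet


@pytest.fixture
def layout50():
    return GenomeLayout([("chr1", 50)])


@pytest.fixture
def layout_small():
    return GenomeLayout([("chr1", 1000), ("chr2", 500)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_regions(pairs, chrom="chr1", label=""):
    return RegionSet([GenomicInterval(chrom, s, e) for s, e in pairs], label=label)


@pytest.fixture
def block_matrix():
    """4x4 contact matrix with two 2-bin blocks and weak cross contacts."""
    from tadvar.contact_matrix import ContactMatrix

    c = np.zeros((4, 4))
    c[0, 1] = c[1, 0] = 8
    c[2, 3] = c[3, 2] = 8
    for i, j in [(0, 2), (0, 3), (1, 2), (1, 3)]:
        c[i, j] = c[j, i] = 1
    return ContactMatrix("chr1", 5000, c)
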