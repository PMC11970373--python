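import numpy as np
import pytest

from k9diff import BinnedTrack, GenomeModel


@pytest.fixture
def genome():
    return GenomeModel([("chrA", 10_000), ("chrB", 5_000)])


@pytest.fixture
def tiny_genome():
    return GenomeModel([("chrA", 2_000)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_track(genome, values_by_chrom, bin_width=200):
    return BinnedTrack(genome, bin_width, {c: np.asarray(v, float)
                                           for c, v in values_by_chrom.items()})
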