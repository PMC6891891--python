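import numpy as np
import pytest

from tilearray import GenomeLayout, Interval, IntervalSet, ProbeTrack


@pytest.fixture
def tiny_layout():
    return GenomeLayout([("chrI", 230218), ("chrII", 813184)])


@pytest.fixture
def small_layout():
    """The 2 x 100 kb unit-test genome."""
    return GenomeLayout([("chr01", 100_000), ("chr02", 100_000)])


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


def make_track(layout, chrom, positions, **values):
    track = ProbeTrack(layout)
    track.add_chrom(chrom, positions, **values)
    return track


@pytest.fixture
def stats_track(small_layout):
    """A signal/pvalue track with one strong 700 bp qualifying run on chr01."""
    pos = np.arange(0, 5000, 10)
    signal = np.zeros(pos.size)
    pvalue = np.ones(pos.size)
    inside = (pos >= 1000) & (pos <= 1699)
    signal[inside] = 1.5
    pvalue[inside] = 0.01
    return make_track(small_layout, "chr01", pos, signal=signal, pvalue=pvalue)
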