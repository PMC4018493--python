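import numpy as np
import pytest

from srp.core_io import GenomicInterval, Peak, SignalTrack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_peak(chrom="chr1", start=100, end=300, summit=None, pvalue=1e-6,
              sample=None, antibody=None, condition=None, name="p"):
    iv = GenomicInterval(chrom, start, end)
    if summit is None:
        summit = (end - start) // 2
    return Peak(iv, summit, 0.0, pvalue, sample, antibody, condition, name)


@pytest.fixture
def uniform_track():
    """1 read/bp on a 10-kb chromosome, library size 1e6."""
    return SignalTrack({"chr1": np.ones(10_000)}, library_size=1e6)
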