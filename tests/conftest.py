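import numpy as np
import pytest

from oscnet.preprocess import TimeSeriesMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_ts(rng):
    """A small broadband ROI x time matrix."""
    return TimeSeriesMatrix(rng.standard_normal((8, 195)), tr_seconds=2.0)


def make_ts(values, tr=2.0, band="broadband"):
    return TimeSeriesMatrix(np.asarray(values, dtype=float), tr_seconds=tr, band=band)
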