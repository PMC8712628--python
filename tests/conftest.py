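import numpy as np
import pytest

from plinet.connectivity import ConnectivityMatrix
from plinet.preprocess import RoiTimeSeriesSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_connectivity(rng):
    """A valid random 68x68 connectivity matrix with distinct weights."""
    w = rng.random((68, 68))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0)
    return ConnectivityMatrix("sub-000", "beta", w)


@pytest.fixture
def sinusoid_series():
    """130 s of a 10 Hz sinusoid on 2 ROIs at 2000 Hz."""
    fs = 2000.0
    t = np.arange(int(130 * fs)) / fs
    x = np.sin(2 * np.pi * 10 * t)
    data = np.vstack([x, np.cos(2 * np.pi * 10 * t)])
    return RoiTimeSeriesSet("sub-sin", fs, ["roi_00", "roi_01"], data)
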