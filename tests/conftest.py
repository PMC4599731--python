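import numpy as np
import pandas as pd
import pytest

from smoltroutes.geometry import default_nsog_geometry
from smoltroutes.io import Detection


@pytest.fixture(scope="session")
def geom():
    return default_nsog_geometry()


@pytest.fixture
def make_detections():
    """Build a detection string for one tag at one array from (minutes, receiver) pairs."""

    def _make(points, tag="tag1", array="NSOG", t0="2013-05-10T00:00:00Z"):
        base = pd.Timestamp(t0)
        return [
            Detection(tag, array, receiver, base + pd.Timedelta(minutes=float(minutes)))
            for minutes, receiver in points
        ]

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20130510)
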