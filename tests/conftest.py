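import numpy as np
import pytest

from hrvlandscape.io import RRSeries


@pytest.fixture
def flat_series():
    """One hour of perfectly regular 800-ms beats."""
    n = 4500
    return RRSeries(rr=np.full(n, 800.0))


@pytest.fixture
def labelled_series():
    rr = np.array([800.0, 40.0, 810.0])
    return RRSeries(rr=rr, beat_label=np.array(["N", "A", "N"]))


def make_series(rr, labels=None, gap=None):
    rr = np.asarray(rr, dtype=float)
    return RRSeries(
        rr=rr,
        beat_label=None if labels is None else np.asarray(labels),
        gap=None if gap is None else np.asarray(gap, dtype=bool),
    )
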