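import numpy as np
import pytest

from percort.io_preprocess import EpochSet


def make_epochs(data, rate=500.0, t0=-5.0, labels=None, state="synthetic"):
    """EpochSet from a (trials, channels, time) array."""
    data = np.asarray(data, dtype=float)
    n_tr, n_ch, n_t = data.shape
    labels = labels or [f"CH{i}" for i in range(n_ch)]
    return EpochSet(
        data=data,
        time_axis=t0 + np.arange(n_t) / rate,
        rate=rate,
        channel_labels=labels,
        channel_xy=np.zeros((n_ch, 2)),
        kept_mask=np.ones(n_tr, dtype=bool),
        state=state,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210804)


@pytest.fixture()
def short_epochs(rng):
    """Small noise epochs (-2..2 s, 8 trials, 2 channels) for filter tests."""
    data = rng.normal(0, 10, size=(8, 2, 2000))
    return make_epochs(data, t0=-2.0)
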