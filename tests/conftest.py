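import numpy as np
import pytest

from timingbci import CENTRAL_18, EpochSet, SimConfig, select, simulate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_epochs(rng):
    """4 trials x 2 channels x 10 samples at 100 Hz, labels +1/-1."""
    return EpochSet(
        data=rng.standard_normal((4, 2, 10)),
        labels=np.array([1, -1, 1, -1]),
        srate=100.0,
        t0_ms=-20.0,
        channel_names=("CZ", "CPZ"),
    )


@pytest.fixture(scope="session")
def default_subject():
    """One synthetic subject at default (both-effects) settings, 18 channels."""
    return select(simulate_subject(SimConfig(seed=77)), channels=CENTRAL_18)


def make_epochs(data, labels, srate=200.0, t0_ms=-500.0, names=None):
    data = np.asarray(data, dtype=float)
    if names is None:
        names = tuple(f"CH{i}" for i in range(data.shape[1]))
    return EpochSet(data=data, labels=np.asarray(labels), srate=srate,
                    t0_ms=t0_ms, channel_names=names)
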