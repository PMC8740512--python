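import numpy as np
import pytest

from grfcast.core import SignalTrace, TrialMeta
from grfcast.synthetic import SimConfig, simulate_trial


@pytest.fixture
def meta():
    return TrialMeta(subject_id="S01", mass=68.1, height=173.0, speed=3.33,
                     slope=0.0, fs_rear=80.0, fs_mid=15.0, fs_fore=5.0)


@pytest.fixture
def noiseless_cfg():
    return SimConfig.noiseless(seed=7)


@pytest.fixture
def noiseless_trial(meta, noiseless_cfg):
    """5 s / 2,000 Hz noiseless trial at 3.2 Hz (16 whole step periods)."""
    return simulate_trial(meta, noiseless_cfg, base_freq_hz=3.2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_trace(samples, rate=500.0, axis="grf_normal_BW", units="BW"):
    return SignalTrace(np.asarray(samples, dtype=float), rate, axis, units)
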