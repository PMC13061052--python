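import numpy as np
import pytest

from hrvpipe import detect
from hrvpipe.simulate import SimulationConfig, generate_study
from hrvpipe.types import RRSeries

EQUAL_NOISE = {"ear_left": 0.1, "ear_right": 0.1, "chest_I": 0.1}  # 20 dB peak SNR


def rr_from_intervals(intervals) -> RRSeries:
    """Build an RR series whose intervals are exactly the given values."""
    x = np.asarray(intervals, dtype=float)
    t = np.concatenate([[0.0], np.cumsum(x)])
    return RRSeries(t, x, np.ones(len(x), dtype=bool))


@pytest.fixture(scope="session")
def snr20_study():
    """One simulated 60 s trial at 400 BPM with 20 dB channels, detected once.

    Returns (config, record, schedule, truth, preprocessed, annotations).
    """
    cfg = SimulationConfig(
        duration_s=60.0, n_trials=1, stim_len_s=30.0, washout_len_s=30.0,
        seed=1, channel_noise=dict(EQUAL_NOISE),
    )
    record, schedule, truth = generate_study(cfg)
    pre = detect.preprocess(record)
    anns = {ch: detect.detect_r_peaks(pre, ch) for ch in record.channel_labels}
    return cfg, record, schedule, truth, pre, anns


@pytest.fixture()
def alt_series():
    """Perfectly alternating 140/160 ms intervals (100 of them)."""
    return rr_from_intervals(np.tile([140.0, 160.0], 50))
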