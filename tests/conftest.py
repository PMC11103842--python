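import numpy as np
import pytest

from bilacc.bilateral import SessionParams
from bilacc.raw_io import RawRecording
from bilacc.synthetic import SynthParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_synth_params():
    """Generator at reduced duration for fast tests; structure unchanged."""
    return SynthParams(
        n_patients=3,
        seed=11,
        duration_h=0.25,
        trailing_idle_range_s=60.0,
    )


@pytest.fixture
def short_session_params():
    """Session thresholds rescaled to the short test recordings."""
    return SessionParams(max_lag_s=30.0, trim_min_run_s=30.0, min_overlap_h=0.05)


def make_recording(samples, arm="left", start=1600000000.0, rate=32.0) -> RawRecording:
    return RawRecording(
        arm_label=arm,
        start_time=start,
        sample_rate_hz=rate,
        samples=np.asarray(samples, dtype=np.int16),
    )


@pytest.fixture
def constant_gravity_recording():
    """1000 samples of a band lying flat: (0, 0, 64) counts = 1 g on z."""
    return make_recording(np.tile([0, 0, 64], (1000, 1)))
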