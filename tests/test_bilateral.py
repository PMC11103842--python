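import numpy as np
import pytest

from bilacc.bilateral import (
    SessionParams,
    build_session,
    estimate_sync_lag,
    trim_trailing_idle,
)
from bilacc.errors import EmptyAfterTrimError, InsufficientOverlapError, TooShortError
from bilacc.preprocess import MagnitudeSeries
from bilacc.raw_io import ClinicalScores, CohortRow
from bilacc.synthetic import SynthParams, simulate_recording_pair

RATE = 32.0 / 48.0


def series(values, n_transient=0, arm="left", start=0.0):
    return MagnitudeSeries(
        arm_label=arm, start_time=start, rate_hz=RATE, values=np.asarray(values, float),
        n_transient=n_transient,
    )


def brute_force_lag(left, right, max_lag):
    """Independent exhaustive search with the documented tie-break."""
    best = None
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            a, b = left[lag:], right
        else:
            a, b = left, right[-lag:]
        m = min(len(a), len(b))
        obj = np.mean(np.abs(a[:m] - b[:m]))
        key = (obj, abs(lag), lag)
        if best is None or key < best[0]:
            best = (key, lag)
    return best[1]


def meta(side="left"):
    from pathlib import Path

    return CohortRow("p1", side, "T1", ClinicalScores(5, 1.0, 1.0), Path("l"), Path("r"))


class TestEstimateSyncLag:
    def test_identical_series_lag_zero(self, rng):
        v = np.abs(rng.normal(size=300))
        assert estimate_sync_lag(v, v, 20) == 0

    def test_recovers_injected_shift(self, rng):
        v = np.abs(rng.normal(size=400))
        # right started 7 samples later: right[j] == left[j + 7]
        assert estimate_sync_lag(v, v[7:], 20) == 7
        assert estimate_sync_lag(v[5:], v, 20) == -5

    def test_matches_exhaustive_oracle_on_noise(self, rng):
        for _ in range(10):
            a = np.abs(rng.normal(size=200))
            b = np.abs(rng.normal(size=200))
            lag = estimate_sync_lag(a, b, 15)
            assert lag == brute_force_lag(a, b, 15)
            assert abs(lag) <= 15

    def test_objective_no_worse_than_zero_lag(self, rng):
        a = np.abs(rng.normal(size=200))
        b = np.abs(rng.normal(size=200))
        lag = estimate_sync_lag(a, b, 15)
        def obj(L):
            x, y = (a[L:], b) if L >= 0 else (a, b[-L:])
            m = min(len(x), len(y))
            return np.mean(np.abs(x[:m] - y[:m]))
        assert obj(lag) <= obj(0)

    def test_tie_breaks_to_smallest_abs_then_negative(self):
        c = np.full(100, 2.0)
        assert estimate_sync_lag(c, c, 10) == 0

    def test_too_short(self):
        with pytest.raises(TooShortError):
            estimate_sync_lag(np.ones(30), np.ones(30), 20)

    def test_shift_recovery_property(self, rng):
        """Exact on noise-free shifts; within ±1 sample at SNR >= 10."""
        base = np.abs(rng.normal(size=500)) * 3.0
        for shift in rng.integers(-12, 13, size=8):
            left = base
            right = base[shift:] if shift >= 0 else np.concatenate([np.zeros(-shift), base])
            assert estimate_sync_lag(left, right, 15) == shift
            noisy = right + rng.normal(scale=0.3, size=len(right))
            assert abs(estimate_sync_lag(left, np.abs(noisy), 15) - shift) <= 1


class TestTrimTrailingIdle:
    def test_trims_long_idle_tail(self):
        rate = RATE
        n_idle = int(600 * rate)
        s = series(np.concatenate([np.ones(200), np.zeros(n_idle)]))
        trimmed, n = trim_trailing_idle(s, eps=0.01, min_run_s=300)
        assert n == n_idle
        assert len(trimmed) == 200

    def test_short_idle_kept(self):
        s = series(np.concatenate([np.ones(200), np.zeros(int(60 * RATE))]))
        trimmed, n = trim_trailing_idle(s, eps=0.01, min_run_s=300)
        assert n == 0
        assert len(trimmed) == len(s)

    def test_all_idle_is_error(self):
        with pytest.raises(EmptyAfterTrimError):
            trim_trailing_idle(series(np.zeros(500)), eps=0.01, min_run_s=300)

    def test_interior_zeros_untouched(self):
        v = np.concatenate([np.ones(50), np.zeros(400), np.ones(50), np.zeros(400)])
        trimmed, n = trim_trailing_idle(series(v), eps=0.01, min_run_s=300)
        assert n == 400
        np.testing.assert_array_equal(trimmed.values, v[:500])

    def test_idempotent(self, rng):
        v = np.concatenate([np.abs(rng.normal(size=300)) + 0.1, np.zeros(300)])
        once, n1 = trim_trailing_idle(series(v), eps=0.01, min_run_s=300)
        twice, n2 = trim_trailing_idle(once, eps=0.01, min_run_s=300)
        assert n2 == 0
        np.testing.assert_array_equal(once.values, twice.values)


class TestBuildSession:
    def test_identical_recordings_lag_zero(self, rng, short_session_params):
        params = SynthParams(duration_h=0.25, trailing_idle_range_s=0.0, sync_offset_range_s=0.0)
        left, right, _ = simulate_recording_pair(0.8, "left", params, np.random.default_rng(0))
        s = build_session(left, right, meta(), session_params=short_session_params)
        assert len(s.left) == len(s.right)
        assert abs(s.applied_lag_samples) <= 1

    def test_recovers_injected_offset_and_trims_idle(self, short_session_params):
        params = SynthParams(duration_h=0.25, trailing_idle_range_s=60.0, seed=5)
        rng = np.random.default_rng(5)
        left, right, truth = simulate_recording_pair(0.7, "left", params, rng)
        s = build_session(left, right, meta(), session_params=short_session_params)
        true_lag = truth.sync_offset_raw_samples / 48.0
        assert abs(s.applied_lag_samples - true_lag) <= 1.0

    def test_insufficient_overlap(self, rng):
        params = SynthParams(duration_h=0.05, trailing_idle_range_s=0.0)
        left, right, _ = simulate_recording_pair(0.8, "left", params, np.random.default_rng(1))
        sp = SessionParams(max_lag_s=10.0, trim_min_run_s=30.0, min_overlap_h=2.0)
        with pytest.raises(InsufficientOverlapError):
            build_session(left, right, meta(), session_params=sp)

    def test_swap_symmetry(self, short_session_params):
        params = SynthParams(duration_h=0.25, trailing_idle_range_s=0.0, seed=9)
        left, right, _ = simulate_recording_pair(0.6, "left", params, np.random.default_rng(9))
        s1 = build_session(left, right, meta("left"), session_params=short_session_params)
        # swap the raw inputs and relabel
        from dataclasses import replace

        lsw = replace(right, arm_label="left")
        rsw = replace(left, arm_label="right")
        s2 = build_session(lsw, rsw, meta("right"), session_params=short_session_params)
        assert s2.applied_lag_samples == -s1.applied_lag_samples
        m = min(len(s1), len(s2))
        np.testing.assert_allclose(s1.left.values[:m], s2.right.values[:m])
        np.testing.assert_allclose(s1.right.values[:m], s2.left.values[:m])
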