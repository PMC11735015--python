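import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hragree.records import HRRecord
from hragree.simulate import SimConfig, simulate_pair
from hragree.sync import (
    ResampledSeries,
    SyncConfig,
    SyncError,
    align_pair,
    find_lag,
    resample_1hz,
    smooth,
)


def brute_force_lag(test_hr, criterion_hr, max_lag, min_overlap=60):
    """Independent exhaustive scan (both series on the same grid origin)."""
    best = None
    for lag in range(-max_lag, max_lag + 1):
        lo = max(0, -lag)
        hi = min(len(criterion_hr), len(test_hr) - lag)
        if hi - lo < min_overlap:
            continue
        d = test_hr[lo + lag : hi + lag] - criterion_hr[lo:hi]
        key = (np.mean(d**2), abs(lag), lag)
        if best is None or key < best[0]:
            best = (key, lag)
    return best[1]


def _series(hr, t0=0.0):
    hr = np.asarray(hr, dtype=float)
    return ResampledSeries(time=np.arange(len(hr)) + t0, hr=hr)


class TestResample:
    def test_linear_interpolation_between_native_samples(self):
        t = np.arange(0.0, 121.0, 2.0)  # native 0.5 Hz sampling
        rec = HRRecord("test", time=t, hr=100.0 + 0.5 * t)
        out = resample_1hz(rec)
        # midpoints filled in linearly: 100, 101, 102, ...
        np.testing.assert_allclose(out.hr, 100.0 + 0.5 * out.time, atol=1e-12)
        assert out.time[0] == 0 and out.time[-1] == 120

    def test_already_1hz_is_unchanged(self, rng):
        hr = 120 + rng.normal(0, 5, 100)
        rec = HRRecord("test", time=np.arange(100.0), hr=hr)
        out = resample_1hz(rec)
        np.testing.assert_array_equal(out.hr, hr)

    def test_irregular_sampling_of_ramp_is_exact(self, rng):
        t = np.sort(rng.uniform(0, 300, 80))
        t[0], t[-1] = 0.0, 300.0
        hr = 100 + 0.2 * t  # a known ramp
        out = resample_1hz(HRRecord("test", time=t, hr=hr))
        np.testing.assert_allclose(out.hr, 100 + 0.2 * out.time, atol=1e-9)

    def test_long_gap_left_missing_and_reported(self):
        t = np.concatenate([np.arange(0, 60.0), np.arange(120.0, 180.0)])
        rec = HRRecord("test", time=t, hr=np.full(len(t), 100.0))
        out = resample_1hz(rec, SyncConfig(max_gap=30))
        assert out.gaps == ((59.0, 120.0),)
        inside = (out.time > 59) & (out.time < 120)
        assert np.all(np.isnan(out.hr[inside]))
        assert not np.any(np.isnan(out.hr[~inside]))

    def test_record_shorter_than_min_overlap_errors(self):
        rec = HRRecord("test", time=np.arange(30.0), hr=np.full(30, 100.0))
        with pytest.raises(SyncError, match="min_overlap"):
            resample_1hz(rec)


class TestFindLag:
    def test_identical_series_lag_zero(self, rng):
        hr = 130 + rng.normal(0, 8, 400)
        assert find_lag(_series(hr), _series(hr)) == 0

    def test_noiseless_shift_recovered(self, rng):
        base = 130 + np.cumsum(rng.normal(0, 1, 500))
        crit = _series(base)
        test = _series(np.concatenate([np.full(7, base[0]), base[:-7]]))  # trails by 7 s
        assert find_lag(test, crit) == 7

    @given(lag=st.integers(-120, 120))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_lag_recovery_property_noiseless(self, lag):
        rng = np.random.default_rng(99)
        base = np.clip(140 + np.cumsum(rng.normal(0, 1.5, 900)), 60, 210)
        test_hr = np.roll(base, lag)  # circular edges are outside the overlap scoring
        got = find_lag(_series(test_hr), _series(base), SyncConfig(max_lag=120))
        assert got == lag

    def test_noisy_shift_matches_brute_force_oracle(self, rng):
        base = 140 + np.cumsum(rng.normal(0, 1.2, 600))
        lag = 23
        test_hr = np.concatenate([np.full(lag, base[0]), base[:-lag]]) + rng.normal(0, 2, 600)
        crit_hr = base + rng.normal(0, 1, 600)
        got = find_lag(_series(test_hr), _series(crit_hr), SyncConfig(max_lag=120))
        assert got == lag
        assert got == brute_force_lag(test_hr, crit_hr, 120)

    def test_no_overlapping_lag_errors(self):
        a = _series(np.full(80, 100.0), t0=0.0)
        b = _series(np.full(80, 100.0), t0=10_000.0)
        with pytest.raises(SyncError, match="overlap"):
            find_lag(a, b)


class TestSmooth:
    def test_constant_series_unchanged(self):
        np.testing.assert_array_equal(smooth(np.full(50, 120.0), 10), np.full(50, 120.0))

    def test_window_one_is_identity(self, rng):
        x = rng.normal(100, 10, 40)
        np.testing.assert_array_equal(smooth(x, 1), x)

    def test_window_covering_series_gives_global_mean(self):
        x = np.array([100.0, 120.0] * 4)
        out = smooth(x, 20)  # 21-point window truncates to the whole 8-point series
        np.testing.assert_allclose(out, np.full(8, x.mean()))

    @given(st.lists(st.floats(30, 240), min_size=3, max_size=60))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_smoothing_never_widens_range(self, values):
        x = np.array(values)
        out = smooth(x, 10)
        assert out.min() >= x.min() - 1e-9
        assert out.max() <= x.max() + 1e-9


class TestAlignPair:
    def test_self_alignment_zero_differences(self, rng):
        hr = np.clip(140 + np.cumsum(rng.normal(0, 1, 300)), 60, 210)
        rec = HRRecord("test", time=np.arange(300.0), hr=hr)
        crit = HRRecord("criterion", time=np.arange(300.0), hr=hr)
        pair = align_pair(rec, crit)
        assert pair.lag_applied == 0
        np.testing.assert_allclose(pair.differences, 0, atol=1e-12)

    def test_delayed_copy_recovers_lag_and_matches(self, rng):
        base = np.clip(150 + np.cumsum(rng.normal(0, 1, 400)), 60, 210)
        crit = HRRecord("criterion", time=np.arange(400.0), hr=base)
        test = HRRecord("test", time=np.arange(395.0), hr=np.concatenate([np.full(5, base[0]), base[:390]]))
        pair = align_pair(test, crit)
        assert pair.lag_applied == 5
        np.testing.assert_allclose(pair.differences, 0, atol=1e-9)

    # interval-style profile whose cycle returns to its starting level:
    # a biased pair over a net-drifting trajectory tilts the plain
    # least-squares lag objective, so the session must not drift overall
    PROFILE = ((120, 130.0), (120, 160.0), (120, 130.0))

    def test_simulated_lag_and_bias_recovered(self):
        cfg = SimConfig(duration=3612, seed=5, lag=12, bias=-10.0,
                        noise_sd_test=2.0, noise_sd_criterion=1.0,
                        hr_profile=self.PROFILE, ou_sd=2.0, test_sample_period=1)
        test, crit, _ = simulate_pair(cfg)
        pair = align_pair(test, crit)
        assert pair.lag_applied == 12
        assert abs(pair.differences.mean() - (-10.0)) < 0.5

    def test_coarse_test_sampling_still_aligns(self):
        # 5 s emission exercises resampling; interpolation limits the lag
        # resolution to about one grid step
        cfg = SimConfig(duration=3612, seed=5, lag=12, bias=-10.0,
                        noise_sd_test=1.0, noise_sd_criterion=1.0,
                        hr_profile=self.PROFILE, ou_sd=2.0, test_sample_period=5)
        test, crit, _ = simulate_pair(cfg)
        pair = align_pair(test, crit)
        assert abs(pair.lag_applied - 12) <= 1
        assert abs(pair.differences.mean() - (-10.0)) < 0.5

    def test_disjoint_time_ranges_error(self):
        a = HRRecord("test", time=np.arange(100.0), hr=np.full(100, 100.0))
        b = HRRecord("criterion", time=np.arange(100.0) + 5000.0, hr=np.full(100, 100.0))
        with pytest.raises(SyncError):
            align_pair(a, b)
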