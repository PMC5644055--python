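"""Peak-calling rules, window shortening, summaries and histograms."""

import numpy as np
import pytest

import calciumpeaks as cp
from calciumpeaks.synthetic import _kernel
from oracles import brute_force_peaks


def _random_instances(n, seed=0):
    """Random short series on a dyadic grid with random dyadic thresholds,
    so tie comparisons are exact in binary floating point."""
    rng = np.random.default_rng(seed)
    for _ in range(n):
        T = int(rng.integers(3, 31))
        x = rng.integers(0, 9, size=T) * 0.25
        rise = float(rng.choice([25, 50, 75, 100]))
        fall = float(rng.choice([25, 50, 75, 100]))
        lb = int(rng.integers(1, 12))
        la = int(rng.integers(1, 12))
        yield x, cp.PeakParams(rise, fall, lb, la)


def test_simple_spike_is_called():
    x = np.array([1.0, 1.0, 2.0, 1.0, 1.0])
    peaks = cp.call_peaks(x, np.arange(5.0), cp.PeakParams(20, 20, 2, 2))
    assert [p.frame_index for p in peaks] == [2]
    assert peaks[0].height == 2.0
    assert peaks[0].rise_time == 1.0
    assert peaks[0].fall_time == 1.0


def test_constant_series_has_no_peaks():
    x = np.ones(50)
    for params in (cp.PeakParams(1, 1, 1, 1), cp.PeakParams(50, 50, 30, 30)):
        assert cp.call_peaks(x, np.arange(50.0), params) == []


def test_endpoints_are_never_peaks():
    x = np.array([5.0, 1.0, 1.0, 1.0, 5.0])
    assert cp.call_peaks(x, np.arange(5.0), cp.PeakParams(10, 10, 4, 4)) == []


def test_matches_brute_force_oracle_on_random_instances():
    for x, params in _random_instances(2000, seed=42):
        got = [p.frame_index for p in
               cp.call_peaks(x, np.arange(x.size, dtype=float), params)]
        expected = brute_force_peaks(x, params.required_rise_pct,
                                     params.required_fall_pct,
                                     params.max_lookback_pts,
                                     params.max_lookahead_pts)
        assert got == expected, (x.tolist(), params)


def test_raising_thresholds_never_increases_peak_count():
    for x, params in _random_instances(400, seed=7):
        t = np.arange(x.size, dtype=float)
        n0 = len(cp.call_peaks(x, t, params))
        import dataclasses
        stricter_rise = dataclasses.replace(
            params, required_rise_pct=params.required_rise_pct + 25)
        stricter_fall = dataclasses.replace(
            params, required_fall_pct=params.required_fall_pct + 25)
        assert len(cp.call_peaks(x, t, stricter_rise)) <= n0
        assert len(cp.call_peaks(x, t, stricter_fall)) <= n0


def test_lookback_truncation_keeps_small_peak_after_large_one():
    """A smaller transient close behind a large one is retained because its
    rise is measured from the intervening trough, not across the big peak."""
    t = np.arange(80) * 0.6
    x = 1.0 + 1.0 * _kernel(t - t[30], 0.5, 2.0) + 0.4 * _kernel(t - t[40], 0.5, 2.0)
    peaks = cp.call_peaks(x, t, cp.PeakParams(30, 30, 8, 10))
    frames = [p.frame_index for p in peaks]
    assert len(frames) == 2
    assert 30 <= frames[0] <= 33 and 40 <= frames[1] <= 43


def test_peaks_are_strict_local_maxima_with_increasing_times():
    for x, params in _random_instances(300, seed=11):
        t = np.arange(x.size, dtype=float)
        peaks = cp.call_peaks(x, t, params)
        times = [p.time for p in peaks]
        assert times == sorted(times) and len(set(times)) == len(times)
        for p in peaks:
            i = p.frame_index
            assert 0 < i < x.size - 1
            assert x[i] > x[i - 1]


def test_summarize_frequency_ten_minute_recording():
    time = np.arange(1001) * 0.6  # 10 min at 600 ms/frame
    mk = lambda f: cp.Peak(f, time[f], 1.5, 0.6, 1.2)
    result = cp.summarize([[mk(10), mk(200), mk(500)]], time)
    assert result.frequencies[0] == pytest.approx(3 / 600.0)
    assert result.mean_frequency == pytest.approx(0.005)


def test_summarize_mean_and_sample_sd():
    time = np.arange(0, 101, 1.0)
    mk = lambda f: cp.Peak(f, float(f), 1.5, 1.0, 1.0)
    result = cp.summarize([[], [mk(10), mk(30), mk(50), mk(70)]], time)
    assert result.mean_events == 2.0
    assert result.sd_events == pytest.approx(2 * np.sqrt(2))
    np.testing.assert_allclose(result.intervals[1], [20, 20, 20])


def test_summarize_no_events_no_division_error():
    result = cp.summarize([[], [], []], np.arange(100.0))
    assert result.mean_frequency == 0.0
    assert result.mean_events == 0.0
    assert result.sd_events == 0.0


def test_histograms_single_peak_and_degenerate_heights():
    time = np.arange(100.0)
    single = cp.summarize([[cp.Peak(5, 5.0, 1.8, 1.0, 2.0)]], time)
    h = cp.peak_height_and_time_histograms(single)
    assert h.heights.counts.sum() == 1
    assert h.rise_times.counts.sum() == 1
    equal = cp.summarize([[cp.Peak(5, 5.0, 1.5, 1.0, 2.0),
                           cp.Peak(20, 20.0, 1.5, 1.0, 2.0)]], time)
    hh = cp.peak_height_and_time_histograms(equal)
    assert (hh.heights.counts > 0).sum() == 1


def test_histograms_empty_result_is_not_an_error():
    h = cp.peak_height_and_time_histograms(cp.summarize([[]], np.arange(10.0)))
    assert h.heights.counts.size == 0


def test_rise_faster_than_fall_with_asymmetric_kernel(quiet_sim):
    """tau_rise=0.5 s < tau_decay=2 s must show up as rise times typically
    shorter than fall times."""
    cfg, ts, _ = quiet_sim
    det = cp.detrend(ts, cp.SmoothingConfig("none"))
    peaks = [cp.call_peaks(row, ts.time, cp.PeakParams(30, 30, 8, 10))
             for row in det.detrended]
    result = cp.summarize(peaks, ts.time, ts.roi_labels)
    h = cp.peak_height_and_time_histograms(result)

    def mode(hist):
        k = int(np.argmax(hist.counts))
        return 0.5 * (hist.edges[k] + hist.edges[k + 1])

    assert mode(h.rise_times) < mode(h.fall_times)


def test_peak_caller_estimator_api(rng):
    X = np.ones((2, 50))
    X[:, 25] = 1.6
    est = cp.PeakCaller(required_rise_pct=30, required_fall_pct=30,
                        max_lookback_pts=5, max_lookahead_pts=5,
                        frame_interval=0.6)
    out = est.fit(X).predict(X)
    assert [len(p) for p in out] == [1, 1]
    assert out[0][0].time == pytest.approx(25 * 0.6)
    assert est.get_params()["required_rise_pct"] == 30


def test_invalid_params_rejected():
    with pytest.raises(cp.ParameterError):
        cp.PeakParams(required_rise_pct=0)
    with pytest.raises(cp.ParameterError):
        cp.PeakParams(max_lookback_pts=0)
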