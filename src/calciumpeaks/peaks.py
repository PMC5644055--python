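"""Calcium-transient detection on de-trended traces.

A candidate point is a strict local maximum of the de-trended series (the
left-most sample of a flat plateau represents the plateau).  Scanning left to
right, a candidate ``v`` at index ``i`` is accepted as a peak when

* **rise** — over a look-back window ending just before ``i`` the series
  rises by at least ``required_rise_pct`` percentage points of the unit
  de-trended baseline: ``v >= min(window) + required_rise_pct/100``.  The
  window starts at most ``max_lookback_pts`` frames before ``i`` and is
  shortened if it would reach past the previously *accepted* peak or past
  the beginning of the data;
* **fall** — within a look-ahead window after ``i`` some sample drops at
  least ``required_fall_pct`` percentage points below the candidate:
  ``value <= v - required_fall_pct/100``.  The window extends at most
  ``max_lookahead_pts`` frames, is clipped at the end of the data, and ends
  immediately before the first sample strictly higher than the candidate.

Because the de-trended series is dimensionless with baseline ~ 1, the rise
and fall thresholds read directly as percent dF/F: a required rise of 20
means the transient must climb 0.20 above the preceding trough.  Thresholds
are deliberately *not* ratios of the local values — ratios would be blind to
any residual multiplicative trend and de-trending would have no effect on
the calls.

The look-back shortening at a previously accepted peak is what lets a small
transient riding the tail of a large one be kept: its rise is measured from
the intervening trough, not from the distant pre-burst baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .errors import ParameterError


@dataclass(frozen=True)
class PeakParams:
    """The four user-set criteria defining a peak."""

    required_rise_pct: float = 20.0
    required_fall_pct: float = 20.0
    max_lookback_pts: int = 30
    max_lookahead_pts: int = 30

    def __post_init__(self) -> None:
        if self.required_rise_pct <= 0 or self.required_fall_pct <= 0:
            raise ParameterError("required rise/fall percents must be > 0")
        if self.max_lookback_pts < 1 or self.max_lookahead_pts < 1:
            raise ParameterError("look-back/look-ahead windows must be >= 1 frame")


@dataclass(frozen=True)
class Peak:
    """A single detected transient.

    ``rise_time`` runs from the look-back-window minimum nearest the peak to
    the peak; ``fall_time`` from the peak to the first sample satisfying the
    fall criterion.
    """

    frame_index: int
    time: float
    height: float
    rise_time: float
    fall_time: float


@dataclass
class PeakCallResult:
    """Per-ROI detected events plus cross-ROI summary statistics."""

    roi_labels: list[str]
    peaks: list[list[Peak]]
    intervals: list[np.ndarray]          # successive differences of event times, s
    frequencies: np.ndarray              # events per second, per ROI
    mean_frequency: float                # mean of per-ROI frequencies
    mean_events: float
    sd_events: float                     # sample sd (ddof=1) of events per ROI
    duration: float                      # recording span used as denominator, s


def _candidate_indices(x: np.ndarray):
    """Strict local maxima, plateau represented by its left-most sample."""
    T = x.size
    out = []
    for i in range(1, T - 1):
        if x[i] <= x[i - 1]:
            continue
        j = i + 1
        while j < T and x[j] == x[i]:
            j += 1
        if j < T and x[j] < x[i]:
            out.append(i)
    return out


def call_peaks(detrended, time, params: PeakParams) -> list[Peak]:
    """Detect peaks in one de-trended trace.

    Parameters
    ----------
    detrended : array-like, shape (T,)
        De-trended trace (baseline ~ 1).
    time : array-like, shape (T,)
        Acquisition times in seconds.
    params : PeakParams

    Returns
    -------
    list of Peak, in strictly increasing time order.
    """
    x = np.asarray(detrended, dtype=float)
    t = np.asarray(time, dtype=float)
    if x.size != t.size:
        raise ParameterError("trace and time must have equal length")
    if x.size < 3:
        raise ParameterError("peak calling needs at least 3 samples")
    rise = params.required_rise_pct / 100.0
    fall = params.required_fall_pct / 100.0

    peaks: list[Peak] = []
    prev_peak = -1
    for i in _candidate_indices(x):
        v = x[i]
        lo = max(i - params.max_lookback_pts, prev_peak + 1, 0)
        if lo >= i:  # empty look-back window (e.g. directly after a peak)
            continue
        window = x[lo:i]
        m = window.min()
        if v < m + rise:
            continue
        fall_idx = -1
        hi = min(i + params.max_lookahead_pts, x.size - 1)
        for j in range(i + 1, hi + 1):
            if x[j] > v:  # look-ahead ends before the first strictly higher point
                break
            if x[j] <= v - fall:
                fall_idx = j
                break
        if fall_idx < 0:
            continue
        # trough index: minimum of the look-back window nearest the peak
        trough = lo + int(np.where(window == m)[0][-1])
        peaks.append(Peak(
            frame_index=i,
            time=float(t[i]),
            height=float(v),
            rise_time=float(t[i] - t[trough]),
            fall_time=float(t[fall_idx] - t[i]),
        ))
        prev_peak = i
    return peaks


def summarize(peaks_per_roi, time, roi_labels=None) -> PeakCallResult:
    """Aggregate per-ROI peak lists into event statistics.

    Frequency uses the full recording span ``time[-1] - time[0]`` as
    denominator; ROIs with no events contribute a frequency of 0 to the
    cross-ROI mean.  The events-per-ROI spread is the sample standard
    deviation (ddof=1; 0 when only one ROI is present).
    """
    t = np.asarray(time, dtype=float)
    duration = float(t[-1] - t[0])
    if duration <= 0:
        raise ParameterError("recording duration must be positive")
    if roi_labels is None:
        roi_labels = [f"ROI_{k + 1:03d}" for k in range(len(peaks_per_roi))]
    counts = np.array([len(p) for p in peaks_per_roi], dtype=float)
    intervals = [np.diff([p.time for p in roi]) for roi in peaks_per_roi]
    freqs = counts / duration
    sd = float(np.std(counts, ddof=1)) if counts.size > 1 else 0.0
    return PeakCallResult(
        roi_labels=list(roi_labels),
        peaks=[list(p) for p in peaks_per_roi],
        intervals=intervals,
        frequencies=freqs,
        mean_frequency=float(freqs.mean()) if counts.size else 0.0,
        mean_events=float(counts.mean()) if counts.size else 0.0,
        sd_events=sd,
        duration=duration,
    )


@dataclass
class HistogramSummary:
    counts: np.ndarray
    edges: np.ndarray


@dataclass
class PeakHistograms:
    heights: HistogramSummary
    rise_times: HistogramSummary
    fall_times: HistogramSummary


def _hist(data: np.ndarray) -> HistogramSummary:
    """Freedman-Diaconis bins with a 10-bin fallback for degenerate spreads."""
    data = np.asarray(data, dtype=float)
    if data.size == 0:
        return HistogramSummary(np.array([], dtype=int), np.array([]))
    if np.ptp(data) == 0:
        v = float(data[0])
        counts, edges = np.histogram(data, bins=1, range=(v - 0.5, v + 0.5))
        return HistogramSummary(counts, edges)
    try:
        edges = np.histogram_bin_edges(data, bins="fd")
        if edges.size < 2 or edges.size > data.size + 100:
            raise ValueError
    except ValueError:
        edges = np.histogram_bin_edges(data, bins=10)
    counts, edges = np.histogram(data, bins=edges)
    return HistogramSummary(counts, edges)


def peak_height_and_time_histograms(result: PeakCallResult) -> PeakHistograms:
    """Histograms of peak heights and of rise/fall times (seconds)."""
    all_peaks = [p for roi in result.peaks for p in roi]
    return PeakHistograms(
        heights=_hist(np.array([p.height for p in all_peaks])),
        rise_times=_hist(np.array([p.rise_time for p in all_peaks])),
        fall_times=_hist(np.array([p.fall_time for p in all_peaks])),
    )


class PeakCaller(BaseEstimator):
    """scikit-learn-style wrapper around :func:`call_peaks`.

    Rows of ``X`` are de-trended ROI traces.  The detector is parametric,
    not learned: ``fit`` validates parameters, ``predict`` returns one list
    of :class:`Peak` per row.
    """

    def __init__(self, required_rise_pct: float = 20.0, required_fall_pct: float = 20.0,
                 max_lookback_pts: int = 30, max_lookahead_pts: int = 30,
                 frame_interval: float = 1.0):
        self.required_rise_pct = required_rise_pct
        self.required_fall_pct = required_fall_pct
        self.max_lookback_pts = max_lookback_pts
        self.max_lookahead_pts = max_lookahead_pts
        self.frame_interval = frame_interval

    def _params(self) -> PeakParams:
        return PeakParams(self.required_rise_pct, self.required_fall_pct,
                          self.max_lookback_pts, self.max_lookahead_pts)

    def fit(self, X, y=None):
        self._params()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X, time=None) -> list[list[Peak]]:
        params = self._params()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if time is None:
            time = np.arange(X.shape[1]) * float(self.frame_interval)
        return [call_peaks(row, time, params) for row in X]
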