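"""Background-trend estimation and divisive de-trending.

Slow multiplicative drifts in baseline fluorescence — photobleaching, focus
drift, indicator leakage — distort transient amplitudes.  The trend is
estimated by one of four smoothers (or a trivial mean) and removed by
dividing the raw trace by it, so the de-trended series is dimensionless with
baseline ~ 1 and ``value - 1`` reads directly as a fractional fluorescence
change (dF/F).

Smoothers
---------
``diffusion``
    Explicit finite-difference heat-equation iteration.  Each step replaces
    ``u_i`` by ``u_i + alpha * (u_{i-1} - 2 u_i + u_{i+1})`` with zero-flux
    (reflecting) boundaries and ``alpha = 0.25``; ``trend_smoothness`` is the
    number of steps.  The equivalent convolution kernel is approximately
    Gaussian with variance ``2 * alpha * steps`` frames^2, and the scheme
    conserves the series sum exactly.
``ema1``
    Causal exponential moving average ``s_i = lam*s_{i-1} + (1-lam)*x_i``
    with ``s_0 = x_0`` and ``lam = 1 - 1/max(k, 1)``; ``k`` is roughly the
    mean age of the weights, so larger values mean longer memory.  Suited to
    recordings whose background keeps changing (pharmacology, overgrown
    cultures).
``ema2``
    Arithmetic mean of the causal EMA and the same EMA run on the
    time-reversed trace.  The current sample is the only point common to
    both passes, so it carries twice the relative weight of its immediate
    neighbours.  Preferred when the whole recording is available and culture
    conditions are static.
``convex``
    The lower convex hull of ``(t_i, x_i)`` anchored at the first and last
    samples — an elastic band stretched under the graph.  Parameter-free;
    the de-trended series is >= 1 everywhere and touches 1 exactly at hull
    contacts.
``none``
    No shape change: the trace is divided by its own mean, so the de-trended
    series has mean exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateTrendError, ParameterError
from .io import TraceSet

METHODS = ("diffusion", "ema1", "ema2", "convex", "none")

DIFFUSION_ALPHA = 0.25  # largest step that keeps the explicit scheme smooth


@dataclass
class SmoothingConfig:
    """Trend-estimation settings.

    ``trend_smoothness`` is ignored by ``convex`` and ``none``.
    """

    method: str = "ema2"
    trend_smoothness: int = 20

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ParameterError(f"unknown smoothing method {self.method!r}")
        if int(self.trend_smoothness) != self.trend_smoothness or self.trend_smoothness < 0:
            raise ParameterError("trend_smoothness must be a non-negative integer")
        self.trend_smoothness = int(self.trend_smoothness)


@dataclass
class DetrendResult:
    """Smoothed trend and the de-trended (raw / trend) traces."""

    trend: np.ndarray       # (R, T), same units as input
    detrended: np.ndarray   # (R, T), dimensionless, baseline ~ 1


def _check_smoothness(trend_smoothness) -> int:
    if int(trend_smoothness) != trend_smoothness or trend_smoothness < 0:
        raise ParameterError("trend_smoothness must be a non-negative integer")
    return int(trend_smoothness)


def smooth_diffusion(trace, trend_smoothness: int) -> np.ndarray:
    """Diffuse a trace for ``trend_smoothness`` explicit heat-equation steps."""
    steps = _check_smoothness(trend_smoothness)
    u = np.asarray(trace, dtype=float).copy()
    if u.size < 3:
        raise ParameterError("diffusion smoothing needs at least 3 samples")
    for _ in range(steps):
        flux = DIFFUSION_ALPHA * np.diff(u)
        u[:-1] += flux
        u[1:] -= flux
    return u


def smooth_ema1(trace, trend_smoothness: int) -> np.ndarray:
    """Causal (backward-looking) exponential moving average."""
    k = _check_smoothness(trend_smoothness)
    x = np.asarray(trace, dtype=float)
    if x.size < 1:
        raise ParameterError("empty trace")
    lam = 1.0 - 1.0 / max(k, 1)
    if lam == 0.0:
        return x.copy()
    y, _ = lfilter([1.0 - lam], [1.0, -lam], x, zi=np.array([lam * x[0]]))
    return y


def smooth_ema2(trace, trend_smoothness: int) -> np.ndarray:
    """Two-sided EMA: mean of the forward pass and the reversed backward pass."""
    x = np.asarray(trace, dtype=float)
    forward = smooth_ema1(x, trend_smoothness)
    backward = smooth_ema1(x[::-1], trend_smoothness)[::-1]
    return 0.5 * (forward + backward)


def lower_hull_indices(time, trace) -> np.ndarray:
    """Vertex indices of the lower convex hull of ``(time, trace)``.

    Andrew monotone-chain restricted to the lower chain; collinear interior
    points are dropped so the result is the minimal vertex set.  The first
    and last samples are always vertices.
    """
    t = np.asarray(time, dtype=float)
    x = np.asarray(trace, dtype=float)
    if t.size != x.size or t.size < 2:
        raise ParameterError("convex envelope needs matching time/trace with >= 2 samples")
    if np.any(np.diff(t) <= 0):
        raise ParameterError("time must be strictly increasing for the convex envelope")
    hull: list[int] = []
    for i in range(t.size):
        while len(hull) >= 2:
            o, a = hull[-2], hull[-1]
            cross = (t[a] - t[o]) * (x[i] - x[o]) - (x[a] - x[o]) * (t[i] - t[o])
            if cross <= 0:  # hull[-1] lies on or above chord o -> i
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull, dtype=int)


def smooth_convex(trace, time=None) -> np.ndarray:
    """Lower convex envelope of the trace, linearly interpolated between vertices."""
    x = np.asarray(trace, dtype=float)
    t = np.arange(x.size, dtype=float) if time is None else np.asarray(time, dtype=float)
    idx = lower_hull_indices(t, x)
    return np.interp(t, t[idx], x[idx])


def _trend_single(trace, time, config: SmoothingConfig) -> np.ndarray:
    if config.method == "diffusion":
        return smooth_diffusion(trace, config.trend_smoothness)
    if config.method == "ema1":
        return smooth_ema1(trace, config.trend_smoothness)
    if config.method == "ema2":
        return smooth_ema2(trace, config.trend_smoothness)
    if config.method == "convex":
        return smooth_convex(trace, time)
    # method == "none": flat trend at the trace mean
    return np.full(np.asarray(trace).shape, float(np.mean(trace)))


class Detrender(TransformerMixin, BaseEstimator):
    """Stateless scikit-learn-style transformer for divisive de-trending.

    Rows of ``X`` are ROIs, columns are frames.  ``transform`` divides each
    row by its estimated trend; nothing is learned from the data, so ``fit``
    only validates parameters (like :class:`sklearn.preprocessing.Normalizer`).

    Parameters
    ----------
    method : str
        One of ``diffusion | ema1 | ema2 | convex | none``.
    trend_smoothness : int
        Diffusion steps / EMA memory in frames; ignored for convex and none.
    """

    def __init__(self, method: str = "ema2", trend_smoothness: int = 20):
        self.method = method
        self.trend_smoothness = trend_smoothness

    def _config(self) -> SmoothingConfig:
        return SmoothingConfig(self.method, self.trend_smoothness)

    def fit(self, X, y=None):
        self._config()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.n_features_in_ = X.shape[1]
        return self

    def trend(self, X, time=None) -> np.ndarray:
        """Estimated per-row background trend, same shape and units as ``X``."""
        cfg = self._config()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.vstack([_trend_single(row, time, cfg) for row in X])

    def transform(self, X, time=None) -> np.ndarray:
        cfg = self._config()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        trend = self.trend(X, time)
        bad = trend <= 0
        if bad.any():
            r, k = np.argwhere(bad)[0]
            raise DegenerateTrendError(
                f"nonpositive trend for ROI index {r} at frame {k}; "
                "cannot de-trend by division"
            )
        out = X / trend
        if cfg.method == "none":
            # renormalize so the mean is exactly 1 despite rounding
            out = out / out.mean(axis=1, keepdims=True)
        return out


def detrend(traces: TraceSet, config: SmoothingConfig | None = None) -> DetrendResult:
    """De-trend every ROI of a :class:`TraceSet` by its smoothed background.

    Raises
    ------
    DegenerateTrendError
        If the trend is zero or negative at any frame (division would emit
        infinities or flip signs); the error names the ROI and frame.
    """
    cfg = config or SmoothingConfig()
    est = Detrender(cfg.method, cfg.trend_smoothness)
    trend = est.trend(traces.values, traces.time)
    bad = trend <= 0
    if bad.any():
        r, k = np.argwhere(bad)[0]
        raise DegenerateTrendError(
            f"nonpositive trend for ROI {traces.roi_labels[r]!r} at frame {k}; "
            "cannot de-trend by division"
        )
    detrended = traces.values / trend
    if cfg.method == "none":
        detrended = detrended / detrended.mean(axis=1, keepdims=True)
    return DetrendResult(trend=trend, detrended=detrended)
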