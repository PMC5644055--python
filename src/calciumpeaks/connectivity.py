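"""Pairwise correlation, peak-train synchrony and raster summaries.

Two complementary views of functional coupling between ROIs:

* **Lagged correlations** work on the *original* traces: entry ``(i, j)`` is
  the maximum Pearson correlation between trace ``i`` and integer temporal
  shifts of trace ``j`` (both directions, overlap-only), so coupling with a
  latency still scores highly.

* **Synchrony index** works on *binarized peak trains*: each trace is
  reduced to 1 near its detected peaks (above the half-maximum of the peak)
  and 0 elsewhere, a generalized autocorrelation is computed per train, and
  pairs are scored by the Pearson correlation of their autocorrelation
  functions, clipped to [0, 1].  Because autocorrelation discards absolute
  event times, the index is large whenever two ROIs fire with similar
  *spacing*, even if one lags the other by many frames.  The zero-lag term
  (just the event rate) is excluded from the pairwise correlation: it
  dominates the variance of every autocorrelation and would make any two
  active trains look synchronized.

A global index — the mean over unordered pairs — summarizes network-wide
synchrony, and average-linkage clustering on ``1 - S`` provides a leaf order
that groups similar ROIs in heat maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .errors import ParameterError
from .io import TraceSet
from .peaks import Peak, PeakCallResult


@dataclass
class ConnectivityResult:
    """Correlation + synchrony matrices with clustering order and global index."""

    correlation_matrix: np.ndarray   # (R, R) in [-1, 1]
    synchrony_matrix: np.ndarray     # (R, R) in [0, 1]
    cluster_order: np.ndarray        # permutation of ROI indices
    global_index: float              # mean of synchrony over unordered pairs


def pairwise_correlations(traces, max_lag: int) -> np.ndarray:
    """Max-over-lags Pearson correlation matrix of the raw traces.

    Parameters
    ----------
    traces : TraceSet or ndarray (R, T)
    max_lag : int
        Largest temporal shift considered, in frames; must be < T/2.

    Constant traces have undefined correlation; their entries are set to 0
    and a warning is emitted.
    """
    X = traces.values if isinstance(traces, TraceSet) else np.atleast_2d(np.asarray(traces, float))
    R, T = X.shape
    if R < 2:
        raise ParameterError("pairwise correlations need at least 2 ROIs")
    if not (0 <= max_lag < T / 2):
        raise ParameterError("max_lag must satisfy 0 <= max_lag < T/2")

    constant = X.std(axis=1) == 0
    if constant.any():
        labels = np.flatnonzero(constant).tolist()
        warnings.warn(f"constant traces at ROI indices {labels}: correlations set to 0",
                      stacklevel=2)

    best = np.full((R, R), -np.inf)
    for d in range(0, max_lag + 1):
        A = X[:, d:]            # trace i advanced by d
        B = X[:, :T - d]        # trace j original support
        Az = _zscore_rows(A)
        Bz = _zscore_rows(B)
        C = (Az @ Bz.T) / (T - d)   # C[i, j] = corr(x_i[d:], x_j[:T-d])
        best = np.maximum(best, np.maximum(C, C.T))
    best = np.clip(best, -1.0, 1.0)
    best[constant, :] = 0.0
    best[:, constant] = 0.0
    np.fill_diagonal(best, 1.0)
    return best


def _zscore_rows(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    sd[sd == 0] = np.inf  # zero-variance rows become all-zero -> corr 0
    return (M - mu) / sd


def binarize(detrended, peaks: list[Peak]) -> np.ndarray:
    """Half-maximum binarization of one de-trended trace.

    For each detected peak of height ``h`` the half-maximum is
    ``(h + 1) / 2`` (local baseline taken as the de-trended resting level 1).
    The contiguous run of frames around the peak where the trace exceeds
    that half-maximum is set to 1; everything else is 0.
    """
    x = np.asarray(detrended, dtype=float)
    train = np.zeros(x.size, dtype=np.uint8)
    for p in peaks:
        half = 0.5 * (p.height + 1.0)
        i = p.frame_index
        if x[i] <= half:
            continue
        lo = i
        while lo > 0 and x[lo - 1] > half:
            lo -= 1
        hi = i
        while hi < x.size - 1 and x[hi + 1] > half:
            hi += 1
        train[lo:hi + 1] = 1
    return train


def generalized_autocorrelation(train, tau_max: int) -> np.ndarray:
    """``A[tau] = sum_t b[t] b[t+tau] / (T - tau)`` for tau = 0..tau_max."""
    b = np.asarray(train, dtype=float)
    T = b.size
    if not (0 < tau_max < T):
        raise ParameterError("tau_max must satisfy 0 < tau_max < T")
    full = np.correlate(b, b, mode="full")
    ac = full[T - 1:T + tau_max]
    return ac / (T - np.arange(tau_max + 1, dtype=float))


def synchrony_index(trains, tau_max: int):
    """Pairwise synchrony matrix, global index, and a cluster leaf order.

    Returns
    -------
    (S, global_index, cluster_order)
        ``S`` is symmetric with unit diagonal and entries in [0, 1].
        Trains with fewer than two events have uninformative
        autocorrelations; their pairwise entries are set to 0 and flagged
        with a warning.
    """
    trains = [np.asarray(b) for b in trains]
    R = len(trains)
    if R < 2:
        raise ParameterError("synchrony needs at least 2 trains")
    degenerate = np.array([int(b.sum()) < 2 for b in trains])
    if degenerate.any():
        warnings.warn(
            f"trains with < 2 events at indices {np.flatnonzero(degenerate).tolist()}: "
            "synchrony set to 0", stacklevel=2)

    A = np.vstack([generalized_autocorrelation(b, tau_max) for b in trains])
    # drop the zero-lag (event-rate) term before correlating
    Az = _zscore_rows(A[:, 1:])
    S = (Az @ Az.T) / (A.shape[1] - 1)
    S = np.clip(S, 0.0, 1.0)
    S[degenerate, :] = 0.0
    S[:, degenerate] = 0.0
    np.fill_diagonal(S, 1.0)

    iu = np.triu_indices(R, k=1)
    global_index = float(S[iu].mean())

    dist = squareform(1.0 - S, checks=False)
    order = leaves_list(linkage(dist, method="average"))
    return S, global_index, np.asarray(order)


def analyze_connectivity(traces: TraceSet, detrended: np.ndarray,
                         peaks_per_roi: list[list[Peak]],
                         max_lag: int | None = None,
                         tau_max: int | None = None) -> ConnectivityResult:
    """Full connectivity analysis: correlations + binarize + synchrony.

    ``max_lag`` and ``tau_max`` default to 10% of the recording length.
    """
    T = traces.n_frames
    if max_lag is None:
        max_lag = max(1, T // 10)
    if tau_max is None:
        tau_max = max(1, T // 10)
    corr = pairwise_correlations(traces, max_lag)
    trains = [binarize(row, pk) for row, pk in zip(detrended, peaks_per_roi)]
    S, global_index, order = synchrony_index(trains, tau_max)
    return ConnectivityResult(correlation_matrix=corr, synchrony_matrix=S,
                              cluster_order=order, global_index=global_index)


def raster(result: PeakCallResult) -> list[tuple[str, float]]:
    """Machine-readable raster: one ``(roi_label, event_time)`` pair per event."""
    return [(label, p.time)
            for label, roi in zip(result.roi_labels, result.peaks)
            for p in roi]
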