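"""An "outstanding-area"-style reference detector and error accounting.

The reference detector reproduces the behaviour of classic
sliding-window-maximum peak finders: every point that is the maximum of its
surrounding window is a candidate, and candidates are scored by an
approximation of the *area* of the peak formation —

    score = (height above the window minimum)
            x (number of window frames above the midpoint between max and min)

Candidates whose score reaches ``selectivity`` are returned.  This scoring
rewards wide formations and presumes a peak exists in every window, so on a
trace that is pure noise the window maximum is always nominated — the
detector's characteristic false-positive mode — while a genuine transient
that is not the tallest point of its window is never considered — its
characteristic false-negative mode.  It is a documented stand-in built to
exhibit those failure modes, not a port of any particular script.

:func:`error_table` scores any detector against ground truth by greedy
nearest-first one-to-one matching within a frame tolerance; unmatched
detections are type I errors (false positives), unmatched true events are
type II errors (false negatives).  :func:`compare_detectors` assembles the
2x2 detector-by-error-type contingency table and its chi-square statistic
(alpha = 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d
from scipy.stats import chi2_contingency

from .errors import ParameterError


@dataclass(frozen=True)
class BaselineParams:
    """Reference-detector settings: prominence-area threshold and window width."""

    selectivity: float = 1.0
    window: int = 25

    def __post_init__(self) -> None:
        if self.selectivity <= 0:
            raise ParameterError("selectivity must be > 0")
        if self.window < 3:
            raise ParameterError("window must be >= 3 frames")


def score_candidates(trace, window: int):
    """Sliding-window maxima and their outstanding-area scores.

    Returns ``(indices, scores)`` for every candidate (a point equal to the
    maximum of its centred window; plateaus keep their left-most sample).
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 3:
        raise ParameterError("need at least 3 samples")
    win_max = maximum_filter1d(x, size=window, mode="nearest")
    is_max = x == win_max
    half_lo = window // 2
    half_hi = window - half_lo  # exclusive upper offset
    indices, scores = [], []
    prev = -2
    for i in np.flatnonzero(is_max):
        if i == prev + 1 and x[i] == x[prev]:  # plateau: keep left-most only
            prev = i
            continue
        prev = i
        lo = max(0, i - half_lo)
        hi = min(x.size, i + half_hi)
        seg = x[lo:hi]
        wmin = seg.min()
        height = x[i] - wmin
        if height == 0:
            continue
        mid = 0.5 * (x[i] + wmin)
        width = int(np.sum(seg > mid))
        indices.append(int(i))
        scores.append(float(height * width))
    return np.asarray(indices, dtype=int), np.asarray(scores, dtype=float)


def call_peaks_baseline(trace, params: BaselineParams) -> list[int]:
    """Indices of candidates whose outstanding-area score reaches selectivity."""
    idx, scores = score_candidates(trace, params.window)
    return [int(i) for i, s in zip(idx, scores) if s >= params.selectivity]


def match_events(detected, truth, tolerance: int):
    """Greedy nearest-first one-to-one matching of detected to true frames.

    Returns ``(matches, false_positive_idx, false_negative_idx)`` where
    matches is a list of ``(detected_frame, true_frame)`` pairs.
    """
    if tolerance < 0:
        raise ParameterError("tolerance must be >= 0")
    det = list(map(int, detected))
    tru = list(map(int, truth))
    pairs = sorted(
        ((abs(d - t), di, ti) for di, d in enumerate(det) for ti, t in enumerate(tru)
         if abs(d - t) <= tolerance),
        key=lambda p: (p[0], p[1], p[2]),
    )
    used_d: set[int] = set()
    used_t: set[int] = set()
    matches = []
    for _, di, ti in pairs:
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
        matches.append((det[di], tru[ti]))
    fp = [det[di] for di in range(len(det)) if di not in used_d]
    fn = [tru[ti] for ti in range(len(tru)) if ti not in used_t]
    return matches, fp, fn


@dataclass
class ErrorCounts:
    """Type I / type II tally for one detector against ground truth."""

    matched: int
    type_i: int   # false positives: detections with no true event in tolerance
    type_ii: int  # false negatives: true events with no detection in tolerance


def error_table(detected_per_roi, truth_frames_per_roi, tolerance: int = 3) -> ErrorCounts:
    """Aggregate matching errors across ROIs.

    Parameters
    ----------
    detected_per_roi : sequence of sequences of frame indices
    truth_frames_per_roi : sequence of sequences of true event frame indices
    tolerance : int
        Maximum |detected - true| distance, in frames, for a match.
    """
    matched = fp = fn = 0
    for det, tru in zip(detected_per_roi, truth_frames_per_roi):
        m, f_p, f_n = match_events(det, tru, tolerance)
        matched += len(m)
        fp += len(f_p)
        fn += len(f_n)
    return ErrorCounts(matched=matched, type_i=fp, type_ii=fn)


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square statistic and p-value on a 2x2 table (no continuity
    correction, matching the textbook N(ad-bc)^2 / marginals formula)."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ParameterError("chi-square table must be 2x2")
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return float(stat), float(p)


@dataclass
class DetectorComparison:
    """Two detectors' error counts and the chi-square test on their 2x2 table."""

    errors_a: ErrorCounts
    errors_b: ErrorCounts
    table: np.ndarray        # rows: detectors; columns: (type I, type II)
    chi2: float
    p_value: float
    significant: bool        # at alpha = 0.05


def compare_detectors(detected_a, detected_b, truth_frames_per_roi,
                      tolerance: int = 3, alpha: float = 0.05) -> DetectorComparison:
    ea = error_table(detected_a, truth_frames_per_roi, tolerance)
    eb = error_table(detected_b, truth_frames_per_roi, tolerance)
    table = np.array([[ea.type_i, ea.type_ii], [eb.type_i, eb.type_ii]], dtype=float)
    stat, p = chi_square_2x2(table)
    return DetectorComparison(errors_a=ea, errors_b=eb, table=table,
                              chi2=stat, p_value=p, significant=p < alpha)
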