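"""Reading and writing ROI fluorescence tables and analysis reports.

Two comma-delimited layouts are supported, mirroring the exports of the two
common acquisition styles:

``wide``
    A header row, first column the time axis (``time`` in seconds or
    ``frame`` as integer indices), one additional column per ROI.  Typical of
    spinning-disk confocal exports where every ROI is sampled on the same
    clock.

``long``
    Three columns ``roi_id, frame|time, intensity`` with a header row, one
    measurement per line.  Typical of plate-based high-content-screening
    exports.

Either layout is auto-detected from the header.  ROIs containing any missing,
blank or non-numeric intensity are removed before analysis (incomplete data
sets arise when the acquisition software drops a dim cell body mid-run) and
listed in the accompanying :class:`FilterReport`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyDataError, FormatError

_TIME_NAMES = {"time", "t", "time_s", "seconds", "time (s)"}
_FRAME_NAMES = {"frame", "frames", "frame_index", "index"}
_ROI_NAMES = {"roi", "roi_id", "label", "object_id"}
_VALUE_NAMES = {"intensity", "value", "fluorescence", "mean_intensity"}


@dataclass
class TraceSet:
    """Time axis plus an ROI-by-time matrix of mean fluorescence.

    Attributes
    ----------
    time : ndarray, shape (T,)
        Acquisition times in seconds, strictly increasing.
    roi_labels : list of str
        Unique ROI identifiers, one per row of ``values``.
    values : ndarray, shape (R, T)
        Mean fluorescence intensity per ROI and frame (arbitrary units).
    """

    time: np.ndarray
    roi_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.roi_labels = [str(x) for x in self.roi_labels]
        if self.time.ndim != 1 or self.time.size < 3:
            raise FormatError("time axis must be one-dimensional with at least 3 frames")
        if np.any(np.diff(self.time) <= 0):
            k = int(np.argmax(np.diff(self.time) <= 0)) + 1
            raise FormatError(f"time axis is not strictly increasing at frame {k}")
        if self.values.shape != (len(self.roi_labels), self.time.size):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.roi_labels)} ROIs x {self.time.size} frames"
            )
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise FormatError("ROI labels are not unique")

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Total recording span in seconds (last time minus first)."""
        return float(self.time[-1] - self.time[0])

    @property
    def frame_interval(self) -> float:
        """Median spacing of successive frames, in seconds."""
        return float(np.median(np.diff(self.time)))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values.T, columns=self.roi_labels)
        df.insert(0, "time", self.time)
        return df


@dataclass
class FilterReport:
    """Outcome of incomplete-ROI removal."""

    kept: int
    dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.kept + len(self.dropped)


def _normalize(name: str) -> str:
    return str(name).strip().lower()


def detect_dialect(path) -> str:
    """Inspect the header row and return ``"wide"`` or ``"long"``."""
    with open(path, "r", encoding="utf-8-sig") as fh:
        header = fh.readline()
    if not header.strip():
        raise FormatError(f"{path}: line 1: empty header row")
    fields = [_normalize(f) for f in header.rstrip("\n").rstrip("\r").split(",")]
    if len(fields) == 3 and fields[0] in _ROI_NAMES and (
        fields[1] in _TIME_NAMES | _FRAME_NAMES
    ) and fields[2] in _VALUE_NAMES:
        return "long"
    if len(fields) >= 2 and fields[0] in _TIME_NAMES | _FRAME_NAMES:
        return "wide"
    raise FormatError(
        f"{path}: line 1: header {header.strip()!r} matches neither the wide "
        "(time, roi, roi, ...) nor the long (roi_id, frame|time, intensity) dialect"
    )


def _time_axis(raw: np.ndarray, col_name: str, frame_interval: float) -> np.ndarray:
    if _normalize(col_name) in _FRAME_NAMES:
        return raw * float(frame_interval)
    return raw


def read_traces(path, dialect: str = "auto", frame_interval: float = 1.0):
    """Read a CSV export into a :class:`TraceSet`, dropping incomplete ROIs.

    Parameters
    ----------
    path : str or Path
        Comma-delimited input file.
    dialect : {"auto", "wide", "long"}
        Layout of the file; ``auto`` resolves by header inspection.
    frame_interval : float
        Seconds per frame, used only when the time column holds integer
        frame indices rather than seconds.

    Returns
    -------
    (TraceSet, FilterReport)

    Raises
    ------
    FormatError
        If the file matches neither dialect or the time axis is invalid.
    EmptyDataError
        If every ROI is dropped by incomplete-data filtering.
    """
    if dialect not in ("auto", "wide", "long"):
        raise FormatError(f"unknown dialect {dialect!r}")
    if dialect == "auto":
        dialect = detect_dialect(path)

    try:
        df = pd.read_csv(path, header=0, dtype=str, skip_blank_lines=True,
                         encoding="utf-8-sig")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc

    if dialect == "wide":
        return _read_wide(df, path, frame_interval)
    return _read_long(df, path, frame_interval)


def _read_wide(df: pd.DataFrame, path, frame_interval: float):
    if df.shape[1] < 2:
        raise FormatError(f"{path}: line 1: wide dialect needs a time column and "
                          "at least one ROI column")
    time_col = df.columns[0]
    if _normalize(time_col) not in _TIME_NAMES | _FRAME_NAMES:
        raise FormatError(f"{path}: line 1: first column {time_col!r} is not a "
                          "recognized time/frame column")
    time_raw = pd.to_numeric(df[time_col], errors="coerce").to_numpy()
    if np.any(~np.isfinite(time_raw)):
        line = int(np.argmax(~np.isfinite(time_raw))) + 2
        raise FormatError(f"{path}: line {line}: non-numeric time value")

    labels = [str(c) for c in df.columns[1:]]
    if len(set(labels)) != len(labels):
        raise FormatError(f"{path}: line 1: duplicate ROI column labels")

    kept_labels: list[str] = []
    kept_rows: list[np.ndarray] = []
    dropped: list[tuple[str, str]] = []
    for label in labels:
        col = pd.to_numeric(df[label], errors="coerce").to_numpy()
        bad = ~np.isfinite(col)
        if bad.any():
            line = int(np.argmax(bad)) + 2
            dropped.append((label, f"missing or non-numeric value at line {line}"))
        else:
            kept_labels.append(label)
            kept_rows.append(col)
    if not kept_labels:
        raise EmptyDataError(f"{path}: all {len(labels)} ROIs dropped as incomplete")

    time = _time_axis(time_raw, time_col, frame_interval)
    ts = TraceSet(time=time, roi_labels=kept_labels, values=np.vstack(kept_rows))
    return ts, FilterReport(kept=len(kept_labels), dropped=dropped)


def _read_long(df: pd.DataFrame, path, frame_interval: float):
    if df.shape[1] != 3:
        raise FormatError(f"{path}: line 1: long dialect needs exactly 3 columns")
    roi_col, time_col, val_col = df.columns
    rois = df[roi_col].astype(str)
    time_raw = pd.to_numeric(df[time_col], errors="coerce").to_numpy()
    if np.any(~np.isfinite(time_raw)):
        line = int(np.argmax(~np.isfinite(time_raw))) + 2
        raise FormatError(f"{path}: line {line}: non-numeric time value")
    vals = pd.to_numeric(df[val_col], errors="coerce").to_numpy()

    axis = np.unique(time_raw)
    order = {t: k for k, t in enumerate(axis)}
    # preserve first-appearance order of ROI labels
    labels = list(dict.fromkeys(rois))
    kept_labels: list[str] = []
    kept_rows: list[np.ndarray] = []
    dropped: list[tuple[str, str]] = []
    for label in labels:
        mask = (rois == label).to_numpy()
        row = np.full(axis.size, np.nan)
        row[[order[t] for t in time_raw[mask]]] = vals[mask]
        if np.all(np.isfinite(row)):
            kept_labels.append(label)
            kept_rows.append(row)
        else:
            k = int(np.argmax(~np.isfinite(row)))
            dropped.append((label, f"missing or non-numeric intensity at frame {k}"))
    if not kept_labels:
        raise EmptyDataError(f"{path}: all {len(labels)} ROIs dropped as incomplete")

    time = _time_axis(axis, time_col, frame_interval)
    ts = TraceSet(time=time, roi_labels=kept_labels, values=np.vstack(kept_rows))
    return ts, FilterReport(kept=len(kept_labels), dropped=dropped)


def write_traces(traces: TraceSet, path) -> None:
    """Write a TraceSet as wide CSV with 12 significant digits.

    Re-reading the file recovers values to that text precision.
    """
    traces.to_dataframe().to_csv(path, index=False, float_format="%.12g")


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_peak_report(result, path) -> None:
    """Write a per-ROI peak report as sectioned CSV.

    One section per ROI (event count, event times, inter-event intervals,
    mean frequency) followed by a footer of cross-ROI aggregates.  Output is
    byte-stable for identical inputs.
    """
    lines = ["section,field,values"]
    for label, peaks, intervals, freq in zip(
        result.roi_labels, result.peaks, result.intervals, result.frequencies
    ):
        times = [p.time for p in peaks]
        lines.append(f"{label},n_events,{len(peaks)}")
        lines.append(",".join([label, "event_times_s"] + [_fmt(t) for t in times]))
        lines.append(",".join([label, "intervals_s"] + [_fmt(d) for d in intervals]))
        lines.append(f"{label},frequency_per_s,{_fmt(freq)}")
    lines.append(f"all_rois,mean_frequency_per_s,{_fmt(result.mean_frequency)}")
    lines.append(f"all_rois,mean_events_per_roi,{_fmt(result.mean_events)}")
    lines.append(f"all_rois,sd_events_per_roi,{_fmt(result.sd_events)}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def write_peak_report_json(result, path) -> None:
    """JSON version of the peak report (same content, machine-friendly)."""
    payload = {
        "rois": [
            {
                "label": label,
                "n_events": len(peaks),
                "event_times_s": [p.time for p in peaks],
                "heights": [p.height for p in peaks],
                "rise_times_s": [p.rise_time for p in peaks],
                "fall_times_s": [p.fall_time for p in peaks],
                "intervals_s": list(map(float, intervals)),
                "frequency_per_s": float(freq),
            }
            for label, peaks, intervals, freq in zip(
                result.roi_labels, result.peaks, result.intervals, result.frequencies
            )
        ],
        "mean_frequency_per_s": result.mean_frequency,
        "mean_events_per_roi": result.mean_events,
        "sd_events_per_roi": result.sd_events,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
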