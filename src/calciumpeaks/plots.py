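"""Matplotlib figure emission (PNG) for the command-line workflow."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def plot_roi_detrending(time, raw, trend, detrended, peaks, path,
                        baseline_peaks=None, label: str = "") -> None:
    """Dual-panel plot: raw + trend above, de-trended with peak markers below.

    Detected peaks are marked with green circles; reference-detector peaks,
    when given as frame indices, with red crosses.
    """
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(8, 5))
    ax1.plot(time, raw, color="black", lw=0.8, label="raw")
    ax1.plot(time, trend, color="red", ls=":", lw=1.2, label="trend")
    ax1.set_ylabel("fluorescence (a.u.)")
    ax1.legend(loc="upper right", fontsize=8)
    ax1.set_title(label)

    ax2.plot(time, detrended, color="black", lw=0.8)
    if peaks:
        ax2.plot([p.time for p in peaks], [p.height for p in peaks],
                 "o", mfc="none", mec="green", ms=8)
    if baseline_peaks is not None and len(baseline_peaks):
        idx = np.asarray(baseline_peaks, dtype=int)
        ax2.plot(np.asarray(time)[idx], np.asarray(detrended)[idx],
                 "x", color="red", ms=7)
    ax2.set_xlabel("time (s)")
    ax2.set_ylabel("de-trended (dF/F + 1)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_raster(pairs, roi_labels, path) -> None:
    """Per-ROI rows of event-time tick marks."""
    fig, ax = plt.subplots(figsize=(8, max(2, 0.12 * len(roi_labels))))
    row = {label: k for k, label in enumerate(roi_labels)}
    xs = [t for _, t in pairs]
    ys = [row[label] for label, _ in pairs]
    ax.scatter(xs, ys, marker="|", s=40, color="black")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("ROI")
    ax.set_ylim(-1, len(roi_labels))
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_heatmap(matrix, path, order=None, title: str = "", vmin=0.0, vmax=1.0) -> None:
    """Matrix heat map, optionally cluster-reordered."""
    M = np.asarray(matrix)
    if order is not None:
        order = np.asarray(order)
        M = M[np.ix_(order, order)]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(M, vmin=vmin, vmax=vmax, cmap="viridis", interpolation="nearest")
    fig.colorbar(im, ax=ax)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_histograms(hists, path) -> None:
    """Peak-height histogram plus overlaid rise/fall-time histograms."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    h = hists.heights
    if h.counts.size:
        ax1.stairs(h.counts, h.edges, fill=True, color="steelblue")
    ax1.set_xlabel("peak height (de-trended)")
    ax1.set_ylabel("count")
    for summary, color, lab in ((hists.rise_times, "seagreen", "rise"),
                                (hists.fall_times, "firebrick", "fall")):
        if summary.counts.size:
            ax2.stairs(summary.counts, summary.edges, fill=False,
                       color=color, label=lab)
    ax2.set_xlabel("time (s)")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
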