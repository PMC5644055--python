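# Methods

## Input model and de-trending

An ROI trace is a series `F(t_i)`, `i = 0..T−1`, of mean fluorescence on a
strictly increasing time axis (frame interval = median of successive time
differences). Slow background changes — photobleaching, focus drift — are
treated as a multiplicative trend: the trace is divided by a smoothed
estimate of itself, so the de-trended series is dimensionless with baseline
≈ 1 and `x − 1` is the fractional fluorescence change ΔF/F. Division (not
subtraction) matches the physics: bleaching attenuates transients and
baseline by the same factor.

Trend estimators (parameter `trend_smoothness`, a non-negative integer in
frames, ignored where noted):

* **diffusion** — explicit heat-equation iteration
  `u ← u + α(u₋₁ − 2u + u₊₁)`, α = 0.25, zero-flux boundaries, run
  `trend_smoothness` times. α = 0.25 keeps the explicit scheme stable and
  smooth; the flux form conserves the series sum exactly, and the impulse
  response is near-Gaussian with variance `2·α·steps` frames².
* **ema1** — causal EMA `s_i = λ s_{i−1} + (1−λ) x_i`, `s₀ = x₀`,
  `λ = 1 − 1/max(k, 1)` so that `k` is approximately the mean age of the
  weights (larger = longer memory). No bias-correction warm-up; the
  initialization term `λ^i x₀` is part of the documented contract.
* **ema2** — mean of the causal EMA and the same EMA applied to the
  time-reversed trace; the current sample is counted by both passes and so
  carries twice the relative weight of its immediate neighbours.
* **convex** — lower convex hull of `(t_i, x_i)` anchored at the first and
  last samples (monotone-chain construction, collinear interior points
  dropped), linearly interpolated between vertices. Parameter-free. The
  de-trended trace is ≥ 1 everywhere and equals 1 exactly at hull contacts.
* **none** — division by the trace mean; the de-trended series keeps its
  shape and has mean exactly 1 (re-normalized after division to remove
  floating-point residue).

A trend that is zero or negative anywhere it would divide raises a
`DegenerateTrendError` naming the ROI and frame; silent clipping would bias
peak heights, and infinities must never propagate.

ROIs containing any missing, blank, or non-numeric intensity are removed
before analysis and listed with reasons — incomplete series arise when
acquisition software drops a dim cell mid-run, and one missing sample
disqualifies the ROI (the strictest reading of incomplete-data removal).

## Peak criterion

Candidates are strict local maxima of the de-trended trace; the left-most
sample of a flat plateau represents the plateau, and the first/last samples
are never peaks (no complete rise or fall window). Scanning left to right,
candidate `v` at index `i` is accepted iff:

* **rise**: `v ≥ min(W_b) + rise/100`, where the look-back window
  `W_b = [max(i − lookback, p + 1, 0), i)` and `p` is the index of the
  previously *accepted* peak;
* **fall**: some `x_j ≤ v − fall/100` for `j` in the look-ahead window
  `W_a = (i, min(i + lookahead, T − 1)]`, truncated immediately before the
  first sample strictly higher than `v`.

Thresholds are **percentage points of the unit de-trended baseline**, i.e.
percent ΔF/F: a required rise of 45 means the trace must climb 0.45 above
the preceding trough. This additive convention was a deliberate design
choice over a ratio (`v ≥ min·(1 + rise/100)`): ratios of nearby samples are
invariant under any slowly varying multiplicative trend, which would make
the peak calls completely independent of the de-trending stage; with
absolute ΔF/F thresholds, de-trending genuinely changes — and in practice
reduces — the false-positive rate on drifting recordings. On a well
de-trended trace (baseline 1) the two conventions coincide.

Rise is measured from the *minimum* of the look-back window (the trough
nearest the peak when the minimum is attained more than once), not from the
window's first sample — the more permissive reading, and the reason the
look-back shortening at a previous peak retains a smaller transient closely
following a large one. Fall is measured relative to the peak value.
Reported per peak: frame, time, height (de-trended value), rise time
(trough → peak) and fall time (peak → first sample meeting the fall
criterion).

Event-rate summaries use the full recording span (`t_{T−1} − t_0`) as the
frequency denominator — not the span between first and last events — and
the spread of events per ROI is the sample standard deviation (ddof = 1; 0
when only one ROI is present). Histograms use Freedman–Diaconis bins with a
fallback (10 equal bins, or a single unit-width bin for zero-spread data).

## Connectivity

**Correlations** act on the *raw* traces, not the called peaks: entry
`(i, j)` is the maximum over integer lags `|d| ≤ max_lag` (default 10% of
T) of the Pearson correlation between trace `i` and the `d`-shifted trace
`j` on their overlap. Maximizing over both shift directions makes the
matrix symmetric by construction. Constant traces have undefined
correlation; their entries are set to 0 and a warning names them.

**Synchrony** acts on binarized peak trains: frames in the contiguous run
around each peak where the de-trended trace exceeds the peak's half-maximum
`(height + 1)/2` (local baseline taken as the de-trended resting level 1)
are set to 1. Per train the generalized autocorrelation
`A(τ) = Σ_t b[t]·b[t+τ] / (T − τ)`, `τ = 0..tau_max` (default 10% of T), is
computed, and the pairwise index is the Pearson correlation of two trains'
autocorrelation functions clipped to `[0, 1]`. The correlation is taken
over `τ ≥ 1`: `A(0)` is simply the event rate and is an order of magnitude
larger than every other lag, so including it would dominate the variance
and drive the index toward 1 for any two active trains. Because
autocorrelation discards absolute time, the index is invariant to a
temporal lag between two similarly spaced trains — its defining property.
Trains with fewer than two events have uninformative autocorrelations;
their pairwise entries are 0 and flagged. The global index is the mean over
unordered pairs, and heat maps are optionally reordered by average-linkage
hierarchical clustering on `1 − S` (dendrogram leaf order). This
formulation is a reconstruction chosen for its provable lag-invariance and
scaling, not a port of any particular implementation.

*Limitation*: binarized events are runs of consecutive ones, so every
train's autocorrelation is elevated at lags shorter than the typical event
width. Populations of independent ROIs whose events merely have similar
durations therefore share that short-lag structure and score well above
zero; the index separates synchronized from independent populations (the
simulator's synchronized bursts raise it further), but its absolute level
should not be read as a calibrated probability. Width-1 event trains (e.g.
Poisson dots) do not share this structure and score near zero.

## Reference detector and error accounting

The comparison detector reproduces the behaviour of classic
window-maximum peak finders: every sample equal to the maximum of its
centred window is a candidate, scored by an "outstanding area"
approximation — (height above the window minimum) × (number of window
frames above the midpoint between maximum and minimum) — and accepted when
the score reaches `selectivity`. Two failure modes follow by construction
and are exercised in the tests: every window of a noisy baseline nominates
its maximum (false positives), and a genuine transient that is not the
tallest point of its window is never considered (false negatives). It is a
documented stand-in exhibiting these modes, not a port of any script.

Detectors are scored by greedy nearest-first one-to-one matching of
detected to true event frames within a tolerance (default 3 frames);
unmatched detections are type I errors, unmatched truths type II. Two
detectors are compared by the Pearson chi-square statistic (no continuity
correction, α = 0.05) on the 2×2 detector-by-error-type table.

Because detectors locate transient *summits* while the simulator records
event *onsets*, ground-truth times are shifted by the kernel's
onset-to-summit delay `s* = ln(τ_d/τ_r)·τ_r τ_d/(τ_d − τ_r)` (≈ 0.92 s ≈
1.5 frames at default kinetics) before matching; without the shift a
constant localization offset would be double-charged as a false positive
plus a false negative.

## Simulator

Traces follow `F(t) = baseline · B(t) · (1 + Σ_k A_k K(t − t_k)) ·
(1 + ε(t))` with:

* `B(t)`: exponential bleach or linear drift losing `magnitude` (default
  30%) of the signal over the recording, or flat;
* `K`: difference-of-exponentials kernel `e^{−s/τ_d} − e^{−s/τ_r}`
  normalized to unit maximum so an event of amplitude `A` peaks at `A`
  ΔF/F; defaults τ_r = 0.5 s, τ_d = 2 s;
* events: per-ROI Poisson, default 0.005 events/frame (≈ 5 per 10-minute
  recording); amplitudes gamma-distributed, mean 0.5 ΔF/F, sd 0.1 (a
  conservative 20% CV for indicator transients in cultured neurons);
* ROIs in a sync group share one event-time sequence with per-ROI Gaussian
  jitter (default sd 1 frame), emulating network bursts;
* `ε`: i.i.d. Gaussian, default sd 0.1 of the local signal (multiplicative,
  like shot noise), i.e. a mean-amplitude-to-noise ratio of 5.

Defaults mirror a 10-minute spinning-disk acquisition: 1000 frames at
600 ms. Trend and noise are multiplicative to match the divisive
de-trending model. All randomness flows through the single seed; identical
seeds give identical output.

What the simulator does *not* emulate: temporally correlated noise,
indicator saturation and nonlinearity (Hill kinetics), motion artifacts,
overlapping-ROI crosstalk, and event-amplitude/rate nonstationarity. Tests
passing on this generator validate the algorithmic contracts, not
performance on any particular microscope's data.

## Detectability at the default noise level

With i.i.d. per-frame noise of sd 0.1 and transients only ~3 frames wide
(τ_d = 2 s at 600 ms frames), detection is governed by window *extremes* of
the noise rather than its per-sample sd: the look-back minimum sits ~1–2 sd
below baseline and false positives require joint rise-and-fall excursions,
so usable thresholds lie near 45–50% ΔF/F. Against a mean amplitude of
0.5 with 20% CV this yields recall ≈ 0.85 at precision ≈ 0.85 at the
matched operating point (rise 45, fall 50, look-back 15, look-ahead 20,
ema2 smoothness 40) — the single-sample threshold rule pays an accuracy
cost relative to an averaging (matched-filter) detector in exchange for its
transparency and parameter interpretability. De-trending's robust benefit
at these conditions is the false-positive rate (roughly halved versus no
de-trending at matched parameters); its effect on recall is small, because
a divisive trend rescales amplitudes by only ±18% around their mean.
Note that with convex de-trending the envelope passes through the *lower*
noise extremes, inflating the de-trended scale (baseline ≈ 1.2 on noisy
data); rise/fall thresholds should be scaled up accordingly when comparing
methods at fixed parameter values.

## Numerical conventions and degenerate inputs

* Time axes must be strictly increasing; duplicate time points are rejected
  at read time (the convex envelope requires it).
* Threshold comparisons are inclusive (`≥` rise, `≤` fall).
* Empty look-back windows (candidate immediately after an accepted peak)
  reject the candidate; they are not errors.
* Zero peaks anywhere produce empty results — empty histograms, all-zero
  binarized trains, zero aggregates — never division errors.
* Chi-square on a table with a zero margin is reported as statistic 0,
  p = 1 (no evidence either way) rather than NaN.
* Peak-report CSV output is byte-stable for identical inputs (fixed `%.6g`
  formatting); trace CSV round-trips at 12 significant digits.
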