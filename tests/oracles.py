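"""Independent brute-force oracles, written directly from the rule statements.

These deliberately re-derive each quantity with naive enumeration so they
share no code path with the package implementation.
"""

import numpy as np


def brute_force_peaks(x, rise_pct, fall_pct, lookback, lookahead):
    """Enumerate every candidate and re-build both windows from scratch.

    Rules: candidates are strict local maxima (left-most sample of a
    plateau); look-back spans at most `lookback` frames, clipped at the
    start of the data and at the previously accepted peak; the candidate
    must exceed the window minimum by rise_pct/100.  Look-ahead spans at
    most `lookahead` frames, clipped at the end of the data and ending
    before the first strictly higher sample; some sample there must lie
    fall_pct/100 below the candidate.
    """
    x = list(map(float, x))
    n = len(x)
    accepted = []
    for i in range(1, n - 1):
        # plateau-left strict local maximum
        if not x[i] > x[i - 1]:
            continue
        j = i + 1
        while j < n and x[j] == x[i]:
            j += 1
        if j >= n or x[j] >= x[i]:
            continue
        prev = accepted[-1] if accepted else None
        back = [k for k in range(n)
                if k < i and k >= i - lookback and (prev is None or k > prev)]
        if not back:
            continue
        if not x[i] >= min(x[k] for k in back) + rise_pct / 100.0:
            continue
        ahead = []
        for k in range(i + 1, n):
            if k > i + lookahead:
                break
            if x[k] > x[i]:
                break
            ahead.append(k)
        if not any(x[k] <= x[i] - fall_pct / 100.0 for k in ahead):
            continue
        accepted.append(i)
    return accepted


def brute_force_lower_hull(t, x):
    """Lower-hull vertices by the minimal-slope walk (O(n^2))."""
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    n = t.size
    verts = [0]
    i = 0
    while i < n - 1:
        slopes = (x[i + 1:] - x[i]) / (t[i + 1:] - t[i])
        best = slopes.min()
        # among minimal slopes pick the farthest point (skips collinear)
        nxt = i + 1 + int(np.flatnonzero(slopes == best)[-1])
        verts.append(nxt)
        i = nxt
    return np.asarray(verts, dtype=int)


def hull_edges_leave_no_point_below(t, x, verts, tol=1e-9):
    """O(n^3)-style check: every hull edge keeps all samples on or above it."""
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    for a, b in zip(verts[:-1], verts[1:]):
        slope = (x[b] - x[a]) / (t[b] - t[a])
        for k in range(t.size):
            line = x[a] + slope * (t[k] - t[a])
            if x[k] < line - tol:
                return False
    return True


def ema_direct(x, k):
    """Causal EMA as an explicit weighted sum including the s0 = x0 term."""
    x = list(map(float, x))
    lam = 1.0 - 1.0 / max(int(k), 1)
    out = []
    for i in range(len(x)):
        acc = (lam ** i) * x[0]
        for a in range(i):
            acc += (1.0 - lam) * (lam ** a) * x[i - a]
        out.append(acc)
    return np.asarray(out)


def diffusion_operator_power(n, steps, alpha=0.25):
    """The explicit diffusion iteration as a dense matrix power."""
    A = np.zeros((n, n))
    for i in range(n):
        A[i, i] = 1.0 - 2.0 * alpha
        if i > 0:
            A[i, i - 1] = alpha
        if i < n - 1:
            A[i, i + 1] = alpha
    # zero-flux boundaries: the missing neighbour reflects onto the cell
    A[0, 0] += alpha
    A[-1, -1] += alpha
    return np.linalg.matrix_power(A, steps)
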