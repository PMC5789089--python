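"""Changepoint-style onset detection on fluorescence intensity traces.

A single robust rule is used throughout the package: estimate the baseline
level and scatter from a pre-event window with median / MAD, then report the
first frame that exceeds ``median + k * MAD`` for ``m`` consecutive frames.
MAD is scaled by 1.4826 so that ``k`` reads in Gaussian-sigma units.
"""

from __future__ import annotations

import numpy as np

__all__ = ["detect_onset", "detect_end", "robust_baseline"]

MAD_SCALE = 1.4826


def robust_baseline(trace: np.ndarray, window: int) -> tuple[float, float]:
    """Median and scaled MAD of the first ``window`` samples of a trace."""
    base = np.asarray(trace[:window], dtype=float)
    if base.size == 0:
        raise ValueError("empty baseline window")
    med = float(np.median(base))
    mad = float(np.median(np.abs(base - med))) * MAD_SCALE
    return med, mad


def detect_onset(
    trace: np.ndarray,
    baseline_window: int = 10,
    k: float = 3.0,
    m: int = 3,
    min_mad: float = 1e-12,
    start: int = 0,
    refine_k: float | None = 1.0,
) -> int | None:
    """First frame at or after ``start`` where ``trace > baseline median +
    k * MAD`` holds for ``m`` consecutive frames; ``None`` if it never does.

    ``start`` restricts the search window; it is used e.g. to look for a
    membrane-bending onset only from clathrin arrival onward, since spurious
    threshold crossings accumulate over long pre-event stretches.

    With ``refine_k`` set, the crossing is refined toward the true start of
    the rise: first backtracked to the first frame of the contiguous stretch
    above ``median + refine_k * MAD`` containing it, then a hinge
    (baseline-plus-ramp changepoint) regression over the surrounding window
    picks the break point with the smallest squared error. The raw k-MAD
    crossing frame depends on the rise slope (a shallow ramp crosses late);
    the changepoint fit makes the reported onset nearly slope-independent,
    so onset lags compare fairly between traces of different brightness and
    rise speed. Pass ``refine_k=None`` for the raw crossing frame.
    """
    trace = np.asarray(trace, dtype=float)
    if len(trace) <= baseline_window + m:
        raise ValueError("trace too short for the requested baseline window")
    med, mad = robust_baseline(trace, baseline_window)
    thresh = med + k * max(mad, min_mad)
    above = trace > thresh
    run = 0
    for i in range(max(0, start), len(above)):
        run = run + 1 if above[i] else 0
        if run >= m:
            cross = i - m + 1
            if refine_k is None:
                return cross
            low = med + refine_k * max(mad, min_mad)
            onset = cross
            while onset > 0 and trace[onset - 1] > low:
                onset -= 1
            # hinge-regression changepoint over the window around the rise
            w0 = max(0, onset - 8)
            w1 = min(len(trace), cross + m)
            tt = np.arange(w0, w1)
            y = trace[w0:w1]
            best_sse, best_c = np.inf, onset
            for c in range(w0, cross + 1):
                X = np.column_stack([np.ones_like(tt), np.clip(tt - c, 0, None)])
                coef, *_ = np.linalg.lstsq(X, y, rcond=None)
                if coef[1] <= 0:
                    continue
                sse = float(((y - X @ coef) ** 2).sum())
                if sse < best_sse:
                    best_sse, best_c = sse, c
            return best_c
    return None


def detect_end(
    trace: np.ndarray,
    onset: int,
    baseline_window: int = 10,
    k: float = 3.0,
    m: int = 3,
    min_mad: float = 1e-12,
    refine_k: float = 1.0,
) -> int:
    """Last frame of the excursion that starts at ``onset``, with hysteresis.

    The search begins at the first frame at/after ``onset`` that clears the
    high (``k`` MAD) threshold — a refined onset may sit at baseline level —
    and the excursion ends when the trace stays below the low
    (``refine_k`` MAD) threshold for ``m`` consecutive frames, symmetric
    with the refined onset. Returns the final frame if it never drops.
    """
    trace = np.asarray(trace, dtype=float)
    med, mad = robust_baseline(trace, baseline_window)
    hi = med + k * max(mad, min_mad)
    lo = med + refine_k * max(mad, min_mad)
    above = np.flatnonzero(trace[onset:] > hi)
    if len(above) == 0:
        return onset
    start = onset + int(above[0])
    below = trace <= lo
    run = 0
    for i in range(start, len(trace)):
        run = run + 1 if below[i] else 0
        if run >= m:
            return i - m
    return len(trace) - 1
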