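"""Shared baseline extraction: (running) percentile with optional
automatic percentile selection via the mode of a kernel density estimate.

A single baseline definition is used project-wide: quality metrics, trace
detrending and dF/F extraction all call :func:`percentile_baseline`.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["percentile_baseline", "auto_percentile"]

_MAX_KDE_POINTS = 10_000


def auto_percentile(trace: np.ndarray) -> float:
    """Percentile level whose value matches the mode of a Gaussian-KDE
    density of the trace.

    The mode of the fluorescence histogram sits at the resting level of the
    trace (transients are sparse positive excursions), so the percentile
    that maps to the mode is a robust baseline level.  Returns a level in
    (0, 50].
    """
    x = np.asarray(trace, dtype=float).ravel()
    if x.size > _MAX_KDE_POINTS:
        step = int(np.ceil(x.size / _MAX_KDE_POINTS))
        x = x[::step]
    if np.ptp(x) == 0:
        return 50.0
    try:
        kde = stats.gaussian_kde(x)  # Silverman bandwidth by default
    except np.linalg.LinAlgError:
        return 50.0
    grid = np.linspace(x.min(), x.max(), 512)
    mode = grid[int(np.argmax(kde(grid)))]
    level = float(stats.percentileofscore(x, mode, kind="mean"))
    return float(np.clip(level, 1e-3, 50.0))


def percentile_baseline(
    trace: np.ndarray,
    frame_rate: float = 30.0,
    window_seconds: float = 100.0,
    percentile: float | None = None,
) -> np.ndarray:
    """Running-percentile baseline of a 1-D trace.

    The percentile is evaluated on non-overlapping blocks of
    ``window_seconds`` (stride equal to the window, then linear
    interpolation between block centers), which keeps the cost linear in T.
    For traces shorter than the window the global percentile is used and
    the baseline is constant.

    Parameters
    ----------
    percentile:
        Fixed percentile level in (0, 50]; if None the level is selected
        automatically with :func:`auto_percentile`.
    """
    y = np.asarray(trace, dtype=float).ravel()
    T = y.size
    if T == 0:
        return y.copy()
    if percentile is None:
        percentile = auto_percentile(y)
    window = int(round(window_seconds * frame_rate))
    if window >= T or window < 2:
        return np.full(T, np.percentile(y, percentile))
    starts = np.arange(0, T, window)
    centers = []
    values = []
    for s in starts:
        block = y[s : s + window]
        centers.append(s + (len(block) - 1) / 2.0)
        values.append(np.percentile(block, percentile))
    if len(values) == 1:
        return np.full(T, values[0])
    return np.interp(np.arange(T), centers, values)
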