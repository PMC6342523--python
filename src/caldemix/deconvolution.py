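"""Sparse nonnegative deconvolution of calcium fluorescence traces.

Calcium dynamics are modeled as a first-order autoregressive process: a
spike at time t adds a unit jump to the trace which then decays
geometrically with per-frame factor gamma.  Given a noisy trace y the
deconvolution problem is

    minimize_{c}  1/2 ||y - c||^2 + lam * sum_t s_t
    subject to    s_t = c_t - gamma * c_{t-1} >= 0  (and optionally
                  s_t = 0 or s_t >= s_min),

solved exactly by a pool-adjacent-violators pass (the AR(1) special case
of the OASIS active-set method): frames are scanned left to right, each
starting its own pool, and adjacent pools are merged while the constraint
between them is violated.  Each merge is the closed-form projection of the
pooled samples onto a single decaying transient, so the sweep terminates
at the global optimum of this convex problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from caldemix._baseline import percentile_baseline

__all__ = ["DeconvParams", "detrend", "oasis_deconvolve", "estimate_ar_noise"]


@dataclass
class DeconvParams:
    """Per-trace deconvolution settings.

    ``ar_coeff`` (gamma) is the per-frame decay of the calcium transient;
    if None it is estimated from the trace's autocovariance.
    ``sparsity_penalty`` (lam) is the L1 weight on spikes;
    ``min_spike`` (s_min) suppresses spikes smaller than this value.
    The default is the simpler lam = 0 with s_min screening.
    """

    ar_coeff: float | None = None
    sparsity_penalty: float = 0.0
    min_spike: float = 0.0
    noise_estimate: float | None = None

    def __post_init__(self) -> None:
        if self.ar_coeff is not None and not (0 <= self.ar_coeff < 1):
            raise ValueError("ar_coeff must lie in [0, 1)")
        if self.sparsity_penalty < 0 or self.min_spike < 0:
            raise ValueError("sparsity_penalty and min_spike must be nonnegative")


def detrend(
    trace: np.ndarray,
    window_seconds: float = 100.0,
    percentile: float | None = None,
    frame_rate: float = 30.0,
) -> np.ndarray:
    """Remove slow non-stationary trends by subtracting a running-percentile
    baseline (the project-wide baseline machinery).  A window of at least
    the trace length reduces to subtracting the global percentile; constant
    traces map to zero."""
    y = np.asarray(trace, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("trace must have at least 2 samples")
    return y - percentile_baseline(y, frame_rate, window_seconds, percentile)


def oasis_deconvolve(
    trace: np.ndarray, params: DeconvParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Denoise a trace and extract its nonnegative spike train.

    Returns ``(denoised, spikes)`` with ``denoised[t] >= gamma *
    denoised[t-1]`` and ``spikes = denoised[t] - gamma * denoised[t-1] >=
    0``.  Pool merging is strictly sequential left to right, so the result
    is deterministic.
    """
    params = params or DeconvParams()
    y = np.asarray(trace, dtype=float).ravel()
    T = y.size
    if T == 0:
        return y.copy(), y.copy()
    if params.ar_coeff is None:
        g, _ = estimate_ar_noise(y)
    else:
        g = params.ar_coeff
    if not (0 <= g < 1):
        raise ValueError(f"AR coefficient {g} outside [0, 1)")
    lam, s_min = params.sparsity_penalty, params.min_spike

    # Absorb the L1 penalty into the data: lam * sum(s) = lam * mu' c with
    # mu_t = 1 - gamma for t < T and mu_T = 1.
    y_eff = y.copy()
    if lam > 0:
        mu = np.full(T, 1.0 - g)
        mu[-1] = 1.0
        y_eff -= lam * mu

    # Pools: value v/w at the pool start, decaying by gamma within the pool.
    v = np.empty(T)
    w = np.empty(T)
    start = np.empty(T, dtype=np.int64)
    length = np.empty(T, dtype=np.int64)
    m = 0  # number of active pools
    for t in range(T):
        v[m], w[m], start[m], length[m] = y_eff[t], 1.0, t, 1
        m += 1
        while m > 1:
            prev, cur = m - 2, m - 1
            gl = g ** length[prev]
            if v[cur] / w[cur] >= gl * (v[prev] / w[prev]) + s_min:
                break
            v[prev] += gl * v[cur]
            w[prev] += gl * gl * w[cur]
            length[prev] += length[cur]
            m -= 1

    c = np.zeros(T)
    for i in range(m):
        h = max(v[i] / w[i], 0.0)
        ln = length[i]
        c[start[i] : start[i] + ln] = h * np.power(g, np.arange(ln))
    s = np.empty(T)
    s[0] = c[0]
    s[1:] = c[1:] - g * c[:-1]
    s[np.abs(s) < 1e-12] = 0.0
    if s_min > 0:
        s[s < s_min] = 0.0
    return c, s


def estimate_ar_noise(trace: np.ndarray, frame_rate: float = 30.0) -> tuple[float, float]:
    """Estimate the AR(1) coefficient and the noise level of a trace.

    The noise level comes from the flat high-frequency half of the power
    spectral density (mean over the upper half of [0, Nyquist]), where the
    slow transient dynamics contribute negligibly.  The AR coefficient is
    the lag-2 / lag-1 autocovariance ratio, which is exactly gamma for an
    AR(1) process observed in white noise; it is clipped to [0, 0.998].
    Degenerate (near-constant or uncorrelated) traces return gamma = 0.
    """
    y = np.asarray(trace, dtype=float).ravel()
    T = y.size
    if T < 4:
        return 0.0, 0.0
    yc = y - y.mean()
    var = float(yc @ yc) / T
    if var <= 0:
        return 0.0, 0.0

    nperseg = int(min(T, 1024))
    freqs, pxx = signal.welch(y, fs=frame_rate, nperseg=nperseg)
    band = freqs >= frame_rate / 4.0
    sigma = float(np.sqrt(np.mean(pxx[band]) * frame_rate / 2.0)) if band.any() else float(np.sqrt(var))

    acov1 = float(yc[:-1] @ yc[1:]) / T
    acov2 = float(yc[:-2] @ yc[2:]) / T
    # Guard against the near-white case where both autocovariances are
    # sampling noise around zero and their ratio is meaningless.
    if acov1 <= max(2.0 / np.sqrt(T), 0.0) * var:
        gamma = 0.0
    else:
        gamma = float(np.clip(acov2 / acov1, 0.0, 0.998))
    return gamma, sigma
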