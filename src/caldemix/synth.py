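"""Synthetic calcium-imaging movies with exact ground truth.

Movies are drawn from the same generative model the extraction pipeline
assumes: a sum of spatially localized rank-one neuronal components, a
low-rank diffuse background and i.i.d. Gaussian noise,

    Y = A C + b f + E,

with unit-norm isotropic Gaussian footprints in ``A`` and AR(1) calcium
transients driven by Bernoulli spike trains in ``C``.  Because every term
of the decomposition is returned alongside the movie, every downstream
stage of the pipeline can be scored against exact ground truth without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from caldemix.movies import Movie

__all__ = [
    "SynthParams",
    "SyntheticGroundTruth",
    "generate_movie",
    "generate_sessions",
]

_PLACEMENT_RETRY_CAP = 1000


@dataclass
class SynthParams:
    """Parameters of the synthetic movie generator.

    ``gaussian_radius`` is the neuron half-width in pixels: footprints are
    isotropic Gaussians with sigma = radius/2 (so the visible soma disc has
    radius ~= ``gaussian_radius``), truncated at 3*radius and normalized to
    unit Euclidean norm.  ``transient_amplitude`` is the trace-domain jump
    per spike; with unit-norm footprints and noise level ``noise_sigma``
    the per-transient peak SNR is amplitude/noise_sigma.
    """

    fov_dims: tuple[int, int] = (64, 64)
    n_frames: int = 1000
    frame_rate: float = 30.0
    n_neurons: int = 20
    gaussian_radius: float = 3.0
    spike_rate: float = 0.5
    ar_coeff: float = 0.95
    transient_amplitude: float = 10.0
    background_rank: int = 2
    noise_sigma: float = 1.0
    seed: int = 0
    min_separation: float | None = None  # defaults to 2*gaussian_radius
    bleach_decay: float = 0.0  # linear multiplicative decay over the movie

    def __post_init__(self) -> None:
        if self.gaussian_radius < 1:
            raise ValueError("gaussian_radius must be >= 1 pixel")
        if not (0 <= self.ar_coeff < 1):
            raise ValueError("ar_coeff must lie in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.n_neurons < 0:
            raise ValueError("n_neurons must be nonnegative")


@dataclass
class SyntheticGroundTruth:
    """Exact decomposition of a generated movie."""

    footprints: np.ndarray  # (d, N), unit-norm columns
    traces: np.ndarray  # (N, T)
    spikes: np.ndarray  # (N, T)
    background_spatial: np.ndarray  # (d, n_b)
    background_temporal: np.ndarray  # (n_b, T)
    centers: np.ndarray  # (N, 2) row, col
    noise_sigma: float
    seed: int = 0
    params: SynthParams | None = field(default=None, repr=False)


def _gaussian_footprint(center: tuple[float, float], fov: tuple[int, int], radius: float) -> np.ndarray:
    rows, cols = fov
    sigma = radius / 2.0
    rr, cc = np.mgrid[0:rows, 0:cols]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    a = np.exp(-d2 / (2 * sigma**2))
    a[d2 > (3 * radius) ** 2] = 0.0  # truncate far tails
    norm = np.linalg.norm(a)
    if norm == 0:
        raise ValueError("degenerate footprint (radius too small for FOV)")
    return (a / norm).ravel()


def _place_centers(rng: np.random.Generator, params: SynthParams) -> np.ndarray:
    """Rejection-sample neuron centers with a minimum pairwise separation.

    Raises an explicit error after a fixed retry budget instead of silently
    clumping neurons together.
    """
    rows, cols = params.fov_dims
    r = params.gaussian_radius
    sep = 2 * r if params.min_separation is None else params.min_separation
    margin = r
    if rows <= 2 * margin or cols <= 2 * margin:
        raise ValueError(f"FOV {params.fov_dims} too small for neuron radius {r}")
    centers: list[tuple[float, float]] = []
    for i in range(params.n_neurons):
        for _ in range(_PLACEMENT_RETRY_CAP):
            cand = (
                rng.uniform(margin, rows - 1 - margin),
                rng.uniform(margin, cols - 1 - margin),
            )
            if all((cand[0] - c[0]) ** 2 + (cand[1] - c[1]) ** 2 >= sep**2 for c in centers):
                centers.append(cand)
                break
        else:
            raise ValueError(
                f"could not place neuron {i + 1}/{params.n_neurons} in FOV "
                f"{params.fov_dims} at separation {sep:.1f} px"
            )
    return np.array(centers).reshape(params.n_neurons, 2)


def _ar1_traces(rng: np.random.Generator, params: SynthParams) -> tuple[np.ndarray, np.ndarray]:
    N, T = params.n_neurons, params.n_frames
    p_spike = min(1.0, params.spike_rate / params.frame_rate)
    spikes = (rng.random((N, T)) < p_spike).astype(np.float64) * params.transient_amplitude
    traces = np.empty((N, T))
    prev = np.zeros(N)
    for t in range(T):
        prev = params.ar_coeff * prev + spikes[:, t]
        traces[:, t] = prev
    return traces, spikes


def _background(rng: np.random.Generator, params: SynthParams) -> tuple[np.ndarray, np.ndarray]:
    """Low-rank neuropil-like background: smooth random spatial surfaces
    paired with slow, rectified random-walk temporal modes."""
    rows, cols = params.fov_dims
    d = rows * cols
    n_b = params.background_rank
    if n_b == 0:
        return np.zeros((d, 0)), np.zeros((0, params.n_frames))
    spatial = np.empty((d, n_b))
    for k in range(n_b):
        surf = ndimage.gaussian_filter(rng.standard_normal((rows, cols)), sigma=min(rows, cols) / 6)
        surf -= surf.min()
        surf += 0.1 * (surf.max() - surf.min() + 1e-12)
        s = surf.ravel()
        spatial[:, k] = s / np.linalg.norm(s)
    # Temporal: slow drift around a positive resting level.  The level is
    # scaled so the per-pixel background baseline is an order of magnitude
    # above the noise floor, as in raw fluorescence where neuropil dominates.
    level = 20.0 * max(params.noise_sigma, 1e-3) * np.sqrt(d)
    temporal = np.empty((n_b, params.n_frames))
    for k in range(n_b):
        walk = np.cumsum(rng.standard_normal(params.n_frames)) / np.sqrt(params.n_frames)
        temporal[k] = np.maximum(level * (1.0 + 0.05 * walk) / n_b, 0.0)
    return spatial, temporal


def generate_movie(params: SynthParams) -> tuple[Movie, SyntheticGroundTruth]:
    """Draw one movie from the generative model; identical seeds give
    bit-identical outputs.

    Returns the movie (pixels x time) and the exact ground-truth
    decomposition used to build it.
    """
    rng = np.random.default_rng(params.seed)
    rows, cols = params.fov_dims
    d, T = rows * cols, params.n_frames

    centers = _place_centers(rng, params)
    A = np.zeros((d, params.n_neurons))
    for i, c in enumerate(centers):
        A[:, i] = _gaussian_footprint(tuple(c), params.fov_dims, params.gaussian_radius)
    C, S = _ar1_traces(rng, params)
    b, f = _background(rng, params)

    data = A @ C + b @ f
    if params.bleach_decay > 0:
        decay = 1.0 - params.bleach_decay * np.arange(T) / max(T - 1, 1)
        data *= decay[None, :]
    if params.noise_sigma > 0:
        data = data + rng.normal(0.0, params.noise_sigma, size=(d, T))

    movie = Movie(data=data, fov_dims=params.fov_dims, frame_rate=params.frame_rate)
    truth = SyntheticGroundTruth(
        footprints=A,
        traces=C,
        spikes=S,
        background_spatial=b,
        background_temporal=f,
        centers=centers,
        noise_sigma=params.noise_sigma,
        seed=params.seed,
        params=params,
    )
    return movie, truth


def _shift_footprints(A: np.ndarray, fov: tuple[int, int], shift: tuple[int, int]) -> np.ndarray:
    """Rigidly translate footprints; pixels shifted out of the FOV are lost."""
    rows, cols = fov
    dy, dx = int(shift[0]), int(shift[1])
    if abs(dy) >= rows or abs(dx) >= cols:
        raise ValueError(f"shift {shift} exceeds FOV {fov}")
    out = np.zeros_like(A)
    for i in range(A.shape[1]):
        img = A[:, i].reshape(rows, cols)
        shifted = np.zeros_like(img)
        src_r = slice(max(0, -dy), rows - max(0, dy))
        src_c = slice(max(0, -dx), cols - max(0, dx))
        dst_r = slice(max(0, dy), rows - max(0, -dy))
        dst_c = slice(max(0, dx), cols - max(0, -dx))
        shifted[dst_r, dst_c] = img[src_r, src_c]
        norm = np.linalg.norm(shifted)
        out[:, i] = shifted.ravel() / norm if norm > 0 else 0.0
    return out


def generate_sessions(
    params: SynthParams,
    n_sessions: int,
    overlap_fraction: float = 0.5,
    shift_pixels: list[tuple[int, int]] | None = None,
) -> tuple[list[tuple[np.ndarray, np.ndarray]], np.ndarray]:
    """Multi-session footprint sets from one master component pool.

    Each session holds a subset of the master pool, rigidly shifted by its
    per-session (dy, dx).  ``overlap_fraction`` is the per-session presence
    probability of each master component, so it is also the expected
    fraction of one session's components shared with the next; 0 partitions
    the pool disjointly across sessions and 1 puts every component in every
    session.

    Returns ``(sessions, table)`` where each session is
    ``(footprints d x N_s, template image rows x cols)`` and ``table`` is the
    master-to-session correspondence: ``table[m, s]`` is the index of master
    component ``m`` in session ``s`` or -1 if absent.
    """
    if n_sessions < 2:
        raise ValueError("need at least 2 sessions")
    if not (0 <= overlap_fraction <= 1):
        raise ValueError("overlap_fraction must be in [0, 1]")
    if shift_pixels is None:
        shift_pixels = [(0, 0)] * n_sessions
    if len(shift_pixels) != n_sessions:
        raise ValueError("one (dy, dx) shift per session required")

    rng = np.random.default_rng(params.seed)
    rows, cols = params.fov_dims
    centers = _place_centers(rng, params)
    N = params.n_neurons
    master = np.zeros((rows * cols, N))
    for i, c in enumerate(centers):
        master[:, i] = _gaussian_footprint(tuple(c), params.fov_dims, params.gaussian_radius)

    if overlap_fraction == 0:
        assignment = rng.integers(0, n_sessions, size=N)
        presence = np.stack([assignment == s for s in range(n_sessions)], axis=1)
    elif overlap_fraction == 1:
        presence = np.ones((N, n_sessions), dtype=bool)
    else:
        presence = rng.random((N, n_sessions)) < overlap_fraction
        for s in range(n_sessions):  # keep every session non-empty
            if not presence[:, s].any():
                presence[rng.integers(0, N), s] = True

    sessions = []
    table = np.full((N, n_sessions), -1, dtype=int)
    for s in range(n_sessions):
        idx = np.flatnonzero(presence[:, s])
        A_s = _shift_footprints(master[:, idx], params.fov_dims, shift_pixels[s])
        keep = np.linalg.norm(A_s, axis=0) > 0
        idx = idx[keep]
        A_s = A_s[:, keep]
        table[idx, s] = np.arange(len(idx))
        template = A_s.max(axis=1).reshape(rows, cols) if A_s.shape[1] else np.zeros((rows, cols))
        sessions.append((A_s, template))
    return sessions, table
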