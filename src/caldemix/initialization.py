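"""Initialization of the bi-convex factorization and summary images.

The factorization Y = A C + b f + E is fit by alternating minimization, so
a good starting point matters.  Three seeding families are provided:

* ``greedy_roi`` / ``rolling_greedy_roi`` — repeatedly seed a component at
  the maximum of the (optionally rolling-window) variance of the spatially
  smoothed movie, fit it by local rank-1 NMF, subtract, and continue.  The
  rolling variant isolates single transients and favors sparsely active
  neurons.
* ``greedy_corr`` — seed at local maxima of the pointwise product of the
  correlation image and the peak-to-noise-ratio image that exceed both
  thresholds; no preset component count is needed.
* ``seeded_initialization`` — start from user-provided (binary or real)
  masks, estimating background from mask-free pixels first.

The correlation image (mean temporal correlation of each pixel with its
neighbors) and its batch-wise maximum are also the summary images used for
manual annotation and FOV alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from caldemix._baseline import percentile_baseline
from caldemix._nmf import hals_footprints, hals_traces, nnmf, rank1_nmf
from caldemix.model import BackgroundModel, ComponentSet
from caldemix.movies import Movie

__all__ = [
    "InitParams",
    "SummaryImage",
    "correlation_image",
    "max_correlation_image",
    "greedy_roi",
    "greedy_corr",
    "seeded_initialization",
    "pnr_image",
]

logger = logging.getLogger(__name__)


@dataclass
class InitParams:
    """Settings for the seeding strategies.

    ``gaussian_width`` is the spatial smoothing scale in pixels, tied to
    the expected neuron radius.  ``rolling_window`` (seconds) switches the
    greedy methods to rolling-window variance with stride window/2.
    """

    method: str = "greedy_roi"
    n_components: int = 10
    gaussian_width: float = 3.0
    rolling_window: float | None = None  # seconds; e.g. 3.0 for the rolling variant
    min_corr: float = 0.8
    min_pnr: float = 5.0
    background_rank: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in {"greedy_roi", "rolling_greedy_roi", "greedy_corr", "seeded"}:
            raise ValueError(f"unknown initialization method {self.method!r}")
        if not (0 <= self.min_corr <= 1):
            raise ValueError("min_corr must lie in [0, 1]")
        if self.n_components < 0:
            raise ValueError("n_components must be nonnegative")


@dataclass
class SummaryImage:
    values: np.ndarray  # (rows, cols)
    kind: str  # mean | correlation | max_correlation | pnr


_NEIGHBOR_OFFSETS = {
    4: [(0, 1), (1, 0)],
    8: [(0, 1), (1, 0), (1, 1), (1, -1)],
}


def correlation_image(movie: Movie, neighborhood: int = 8) -> SummaryImage:
    """Mean Pearson correlation of each pixel's time series with those of
    its 4- or 8-neighbors; border pixels average over existing neighbors
    only.  Zero-variance pixels contribute correlation 0 (logged)."""
    if neighborhood not in _NEIGHBOR_OFFSETS:
        raise ValueError("neighborhood must be 4 or 8")
    if movie.n_frames < 2:
        raise ValueError("correlation image needs at least 2 frames")
    rows, cols = movie.fov_dims
    X = movie.data.reshape(rows, cols, movie.n_frames).astype(float)
    X = X - X.mean(axis=2, keepdims=True)
    norm = np.linalg.norm(X, axis=2)
    flat = norm == 0
    if flat.any():
        logger.info("correlation_image: %d zero-variance pixels treated as correlation 0", flat.sum())
    Z = np.divide(X, norm[..., None], out=np.zeros_like(X), where=~flat[..., None])

    acc = np.zeros((rows, cols))
    count = np.zeros((rows, cols))
    for dr, dc in _NEIGHBOR_OFFSETS[neighborhood]:
        a_r = slice(max(0, -dr), rows - max(0, dr))
        a_c = slice(max(0, -dc), cols - max(0, dc))
        b_r = slice(max(0, dr), rows - max(0, -dr))
        b_c = slice(max(0, dc), cols - max(0, -dc))
        prod = np.einsum("ijt,ijt->ij", Z[a_r, a_c], Z[b_r, b_c])
        acc[a_r, a_c] += prod
        acc[b_r, b_c] += prod
        count[a_r, a_c] += 1
        count[b_r, b_c] += 1
    values = np.divide(acc, count, out=np.zeros_like(acc), where=count > 0)
    return SummaryImage(values=values, kind="correlation")


def max_correlation_image(
    movie: Movie, batch_seconds: float = 33.0, neighborhood: int = 8
) -> SummaryImage:
    """Pointwise maximum of per-batch correlation images over consecutive
    batches (default 33 s per batch).  Suppresses neurons that are only
    briefly active less than the full-movie correlation image does."""
    T = movie.n_frames
    batch = int(round(batch_seconds * movie.frame_rate))
    if batch < 2:
        raise ValueError("batch length must cover at least 2 frames")
    out = None
    for t0 in range(0, T, batch):
        t1 = min(t0 + batch, T)
        if t1 - t0 < 2:
            break
        sub = Movie(movie.data[:, t0:t1], movie.fov_dims, movie.frame_rate)
        ci = correlation_image(sub, neighborhood).values
        out = ci if out is None else np.maximum(out, ci)
    if out is None:
        raise ValueError("movie shorter than 2 frames")
    return SummaryImage(values=out, kind="max_correlation")


def _smooth_frames(data: np.ndarray, fov: tuple[int, int], sigma: float) -> np.ndarray:
    rows, cols = fov
    stack = data.reshape(rows, cols, -1)
    return ndimage.gaussian_filter(stack, sigma=(sigma, sigma, 0)).reshape(data.shape)


def _variance_image(SM: np.ndarray, window: int | None, stride: int | None) -> np.ndarray:
    """Per-pixel variance of a (d, T) array, either global or the maximum
    over rolling windows."""
    T = SM.shape[1]
    if window is None or window >= T:
        return SM.var(axis=1)
    stride = max(stride or window // 2, 1)
    csum = np.cumsum(np.concatenate([np.zeros((SM.shape[0], 1)), SM], axis=1), axis=1)
    csum2 = np.cumsum(np.concatenate([np.zeros((SM.shape[0], 1)), SM**2], axis=1), axis=1)
    best = np.zeros(SM.shape[0])
    for t0 in range(0, T - window + 1, stride):
        t1 = t0 + window
        mean = (csum[:, t1] - csum[:, t0]) / window
        var = (csum2[:, t1] - csum2[:, t0]) / window - mean**2
        np.maximum(best, var, out=best)
    return best


def greedy_roi(movie: Movie, params: InitParams) -> tuple[np.ndarray, np.ndarray]:
    """Greedy seeding at successive maxima of smoothed-movie variance.

    Each seed is fit by rank-1 NMF in a local square of side
    ``4 * gaussian_width + 1`` around the variance peak and its explained
    activity subtracted before the next seed.  With ``rolling_window`` set
    the variance is the maximum over rolling windows (stride window/2),
    which better isolates sparse transients.
    """
    K = params.n_components
    rows, cols = movie.fov_dims
    d, T = movie.n_pixels, movie.n_frames
    if K > d:
        raise ValueError(f"cannot seed {K} components in {d} pixels")
    if K == 0:
        return np.zeros((d, 0)), np.zeros((0, T))

    sigma = params.gaussian_width / 2.0
    R = movie.data - np.percentile(movie.data, 20, axis=1, keepdims=True)
    SM = _smooth_frames(R, movie.fov_dims, sigma)
    window = None
    if params.rolling_window is not None:
        window = max(2, int(round(params.rolling_window * movie.frame_rate)))

    half = int(2 * params.gaussian_width)
    A0 = np.zeros((d, K))
    C0 = np.zeros((K, T))
    n_found = 0
    for _ in range(K):
        var_img = _variance_image(SM, window, None if window is None else window // 2)
        p = int(np.argmax(var_img))
        if var_img[p] <= 0:
            break
        pr, pc = divmod(p, cols)
        r0, r1 = max(0, pr - half), min(rows, pr + half + 1)
        c0, c1 = max(0, pc - half), min(cols, pc + half + 1)
        box_rows = np.arange(r0, r1)
        box_pix = (box_rows[:, None] * cols + np.arange(c0, c1)[None, :]).ravel()
        patch = R[box_pix]
        center_local = (pr - r0) * (c1 - c0) + (pc - c0)
        a_loc, c = rank1_nmf(patch, n_iter=10, tol=1e-4, init_c=np.maximum(patch[center_local], 0))
        if a_loc.max() == 0 or c.max() == 0:
            break
        A0[box_pix, n_found] = a_loc
        C0[n_found] = c
        # subtract the explained activity from both the raw and the
        # smoothed residual (smoothing is linear)
        R[box_pix] -= np.outer(a_loc, c)
        a_img = np.zeros(d)
        a_img[box_pix] = a_loc
        SM -= np.outer(_smooth_frames(a_img[:, None], movie.fov_dims, sigma).ravel(), c)
        n_found += 1
    return A0[:, :n_found], C0[:n_found]


def pnr_image(movie: Movie, transient_seconds: float = 0.4) -> SummaryImage:
    """Peak-to-noise ratio image: per pixel, the maximum of the temporally
    smoothed median-subtracted trace divided by its half-normal noise
    level."""
    data = movie.data
    med = np.median(data, axis=1, keepdims=True)
    dev = data - med
    sub = np.where(dev <= 0, dev, np.nan)
    with np.errstate(invalid="ignore"):
        noise = np.nanstd(sub, axis=1) / np.sqrt(1 - 2 / np.pi)
    noise[~np.isfinite(noise) | (noise <= 0)] = np.inf
    n_s = max(int(np.ceil(transient_seconds * movie.frame_rate)), 1)
    smooth = ndimage.uniform_filter1d(dev, size=n_s, axis=1)
    peak = smooth.max(axis=1)
    values = np.maximum(peak, 0) / noise
    return SummaryImage(values=values.reshape(movie.fov_dims), kind="pnr")


def greedy_corr(movie: Movie, params: InitParams) -> tuple[np.ndarray, np.ndarray]:
    """Seed components at local maxima of (correlation image x PNR image)
    exceeding both ``min_corr`` and ``min_pnr``; no preset count needed."""
    rows, cols = movie.fov_dims
    ci = correlation_image(movie).values
    pnr = pnr_image(movie).values
    product = ci * pnr

    win = 2 * int(params.gaussian_width) + 1
    local_max = product == ndimage.maximum_filter(product, size=win)
    candidates = local_max & (ci >= params.min_corr) & (pnr >= params.min_pnr)
    seeds = np.argwhere(candidates)
    if seeds.size == 0:
        return np.zeros((movie.n_pixels, 0)), np.zeros((0, movie.n_frames))
    order = np.argsort(product[candidates])[::-1]
    seeds = seeds[order]

    half = int(2 * params.gaussian_width)
    R = movie.data - np.percentile(movie.data, 20, axis=1, keepdims=True)
    footprints, traces = [], []
    for pr, pc in seeds:
        r0, r1 = max(0, pr - half), min(rows, pr + half + 1)
        c0, c1 = max(0, pc - half), min(cols, pc + half + 1)
        box_pix = (np.arange(r0, r1)[:, None] * cols + np.arange(c0, c1)[None, :]).ravel()
        patch = R[box_pix]
        center_local = (pr - r0) * (c1 - c0) + (pc - c0)
        a_loc, c = rank1_nmf(patch, n_iter=10, tol=1e-4, init_c=np.maximum(patch[center_local], 0))
        if a_loc.max() == 0 or c.max() == 0:
            continue
        a = np.zeros(movie.n_pixels)
        a[box_pix] = a_loc
        footprints.append(a)
        traces.append(c)
        R[box_pix] -= np.outer(a_loc, c)
    if not footprints:
        return np.zeros((movie.n_pixels, 0)), np.zeros((0, movie.n_frames))
    return np.stack(footprints, axis=1), np.stack(traces, axis=0)


def seeded_initialization(
    movie: Movie,
    masks: np.ndarray,
    background_rank: int = 2,
    hals_passes: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Initialize (A, C, b, f) from known masks.

    ``masks`` is (d, N), binary or nonnegative real.  Temporal background
    f is estimated by rank-``background_rank`` NMF on the pixels no mask
    covers, b by nonnegative regression, C by nonnegative projection onto
    the masks and A by mask-constrained nonnegative regression, followed
    by a short HALS polish.
    """
    Y = movie.data
    d, T = Y.shape
    masks = np.asarray(masks, dtype=float)
    if masks.ndim != 2 or masks.shape[0] != d:
        raise ValueError("masks must be (n_pixels, n_components)")
    N = masks.shape[1]
    if N == 0:
        logger.warning("seeded_initialization: empty mask set; returning background-only model")
        b, f = nnmf(Y, background_rank, seed=seed)
        return np.zeros((d, 0)), np.zeros((0, T)), b, f

    covered = masks.max(axis=1) > 0
    if covered.all():
        raise ValueError("no background pixels: masks cover the entire FOV")

    free = ~covered
    _, f = nnmf(Y[free], background_rank, seed=seed)
    if background_rank > 0 and f.shape[0] > 0:
        b = hals_footprints(Y, np.zeros((d, f.shape[0])), f, n_passes=5)
    else:
        b, f = np.zeros((d, 0)), np.zeros((0, T))

    M = (masks > 0).astype(float)
    resid = Y - b @ f
    C = np.maximum(np.linalg.lstsq(M, resid, rcond=None)[0], 0.0)
    support = M > 0
    A = hals_footprints(resid, masks * 0.0, C, support=support, n_passes=5)

    for _ in range(hals_passes):
        b = hals_footprints(Y - A @ C, b, f, n_passes=1)
        f = hals_traces(Y - A @ C, b, f, n_passes=1)
        C = hals_traces(Y - b @ f, A, C, n_passes=1)
        A = hals_footprints(Y - b @ f, A, C, support=support, n_passes=1)
    return A, C, b, f


def initialize(movie: Movie, params: InitParams) -> tuple[ComponentSet, BackgroundModel]:
    """Dispatch on ``params.method`` and wrap the result with a low-rank
    background estimated from the residual."""
    if params.method in {"greedy_roi", "rolling_greedy_roi"}:
        p = params
        if params.method == "rolling_greedy_roi" and p.rolling_window is None:
            from dataclasses import replace

            p = replace(params, rolling_window=3.0)
        A, C = greedy_roi(movie, p)
    elif params.method == "greedy_corr":
        A, C = greedy_corr(movie, params)
    else:
        raise ValueError("seeded initialization requires masks; call seeded_initialization")
    b, f = nnmf(movie.data - A @ C, params.background_rank, seed=params.seed)
    comps = ComponentSet(A, C)
    bg = BackgroundModel(kind="low_rank", spatial=b, temporal=f)
    return comps, bg
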