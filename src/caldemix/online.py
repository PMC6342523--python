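"""Streaming source extraction: frame-by-frame demixing with on-the-fly
component detection.

After a short initialization, each incoming frame updates the temporal
traces by block-coordinate descent (components whose footprints do not
overlap form a group and are updated jointly), rolls a buffer of residual
frames, and accumulates the sufficient statistics

    stat_yc = Y_{1:t} [C; f]' / t,    stat_cc = [C; f] [C; f]' / t,

which are all that is needed to update spatial footprints without storing
the movie.  New components are detected from the residual buffer: local
maxima of its positive-part energy image (after spatial high-pass
filtering) are screened by a footprint classifier and a trace-SNR test
before being added with zero past activity.  Footprint updates are spread
over frames by a counter schedule that guarantees every footprint is
refreshed at least once every ``shape_update_period`` frames while
skipping frames on which components were just added.  Multiple epochs
replay the movie with detection still enabled, letting late-detected
components back-fill their traces.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

from caldemix._nmf import hals_footprints, hals_traces, nnmf, rank1_nmf
from caldemix.deconvolution import DeconvParams, oasis_deconvolve
from caldemix.initialization import InitParams, greedy_roi
from caldemix.model import BackgroundModel, ComponentSet
from caldemix.movies import Movie, load_movie
from caldemix.quality import classify_footprints, detect_duplicates, peak_snr

__all__ = [
    "OnlineParams",
    "OnlineState",
    "initialize_online",
    "process_frame",
    "find_new_components",
    "shape_update_schedule",
    "update_shapes",
    "run_online",
]

logger = logging.getLogger(__name__)


@dataclass
class OnlineParams:
    """Streaming-pipeline settings.

    ``buffer_frames`` defaults to max(100, ceil(3.3 * frame_rate));
    candidate components must pass both the classifier screen
    (score >= ``classifier_threshold`` on the mean residual crop) and a
    trace peak-SNR over the buffer of at least ``snr_threshold``.
    """

    init_frames: int = 200
    init_mode: str = "bare"  # bare | batch | seeded
    init_components: int = 2
    candidates_per_frame: int = 5
    buffer_frames: int | None = None
    shape_update_period: int = 200
    epochs: int = 2
    classifier_threshold: float = 0.6
    snr_threshold: float = 1.2
    neuron_radius: float = 3.0
    background_rank: int = 2
    transient_seconds: float = 0.4
    trace_passes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.init_mode not in {"bare", "batch", "seeded"}:
            raise ValueError("init_mode must be bare, batch or seeded")
        if self.candidates_per_frame < 0:
            raise ValueError("candidates_per_frame must be nonnegative")

    def resolved_buffer(self, frame_rate: float) -> int:
        if self.buffer_frames is not None:
            return self.buffer_frames
        return max(100, int(np.ceil(3.3 * frame_rate)))


@dataclass
class OnlineState:
    """All running quantities of the streaming pipeline."""

    footprints: np.ndarray  # A: (d, K)
    bg_spatial: np.ndarray  # b: (d, n_b)
    trace_values: np.ndarray  # current [c_t] (K,)
    bg_values: np.ndarray  # current [f_t] (n_b,)
    stat_yc: np.ndarray  # (d, K + n_b)
    stat_cc: np.ndarray  # (K + n_b, K + n_b)
    residual_buffer: np.ndarray  # (d, l_b), oldest first
    groups: list[np.ndarray]
    update_counter: np.ndarray  # q: (K,)
    t: int  # frames accumulated into the statistics
    epoch: int
    fov_dims: tuple[int, int]
    frame_rate: float
    trace_history: np.ndarray  # (K, T) traces of the current epoch
    bg_history: np.ndarray  # (n_b, T)
    frame_index: int  # position within the current epoch
    new_component_log: list[tuple[int, int]] = field(default_factory=list)  # (t, index)

    @property
    def n_components(self) -> int:
        return self.footprints.shape[1]


def _partition_groups(A: np.ndarray) -> list[np.ndarray]:
    """Greedy coloring of the footprint-overlap graph; components in one
    group have pairwise non-overlapping footprints."""
    K = A.shape[1]
    if K == 0:
        return []
    overlap = (A.T @ A) > 0
    np.fill_diagonal(overlap, False)
    color = np.full(K, -1, dtype=int)
    for i in range(K):
        used = set(color[j] for j in np.flatnonzero(overlap[i]) if color[j] >= 0)
        c = 0
        while c in used:
            c += 1
        color[i] = c
    return [np.flatnonzero(color == c) for c in range(color.max() + 1)]


def shape_update_schedule(
    q: np.ndarray | None,
    A: np.ndarray,
    newly_added: list[int],
    update_period: int,
) -> tuple[np.ndarray, np.ndarray]:
    """One step of the distributed shape-update schedule.

    Counters start logarithmically spaced in (1, 2] (q_i = 2^(i/K)) and
    are multiplied by 0.5^(1/T_u) every frame, so each counter crosses 1
    at most T_u frames after it was last topped up: every footprint is
    updated at least once per ``update_period`` frames.  On frames where
    components were added no shapes are updated; instead the counters of
    components overlapping an addition are zeroed, forcing their update on
    the next frame.

    Returns ``(indices_to_update, q)``.
    """
    K = A.shape[1]
    if q is None:
        q = np.power(2.0, np.arange(1, K + 1) / max(K, 1))
    q = q * 0.5 ** (1.0 / update_period)
    if not newly_added:
        due = np.flatnonzero(q <= 1.0)
        q[due] += 1.0
        return due, q
    touched: set[int] = set()
    for j in newly_added:
        touched.update(np.flatnonzero(A.T @ A[:, j] > 0))
        touched.discard(j)
    q[sorted(touched)] = 0.0
    return np.array([], dtype=int), q


def update_shapes(
    stat_yc: np.ndarray,
    stat_cc: np.ndarray,
    footprints: np.ndarray,
    bg_spatial: np.ndarray,
    indices: np.ndarray,
    fov_dims: tuple[int, int],
    support_dilation: int = 1,
) -> np.ndarray:
    """Dictionary-learning footprint update from sufficient statistics.

    For each scheduled component i:
    a_i <- max(a_i + (stat_yc[:, i] - [A, b] stat_cc[:, i]) / stat_cc[i, i], 0),
    restricted to the dilated current support.  Only listed indices
    change; never-active components (zero statistic) are skipped.
    """
    A = footprints
    if len(indices) == 0:
        return A
    K = A.shape[1]
    AB = np.concatenate([A, bg_spatial], axis=1) if bg_spatial.size else A
    structure = ndimage.generate_binary_structure(2, 2)
    for i in indices:
        denom = stat_cc[i, i]
        if denom == 0:
            logger.debug("update_shapes: component %d never active; skipped", i)
            continue
        step = (stat_yc[:, i] - AB @ stat_cc[:, i]) / denom
        new = np.maximum(AB[:, i] + step, 0.0)
        if i < K:  # neuronal footprints stay local; background modes are global
            mask = (A[:, i] > 0).reshape(fov_dims)
            mask = ndimage.binary_dilation(mask, structure=structure, iterations=support_dilation)
            new[~mask.ravel()] = 0.0
            A[:, i] = new
        else:
            bg_spatial[:, i - K] = new
        AB[:, i] = new
    return A


def initialize_online(prefix: Movie, params: OnlineParams, masks: np.ndarray | None = None,
                      batch_params=None, total_frames: int | None = None) -> OnlineState:
    """Build the initial state from the first ``init_frames`` frames.

    ``bare`` mode fits only the background plus a handful of components on
    the prefix (everything else is found during streaming); ``batch``
    runs the full batch pipeline on the prefix; ``seeded`` starts from
    provided masks.
    """
    t_prime = prefix.n_frames
    l_b = params.resolved_buffer(prefix.frame_rate)
    if t_prime < l_b:
        raise ValueError(f"init prefix of {t_prime} frames is shorter than the buffer ({l_b})")
    Y = prefix.data
    d = prefix.n_pixels
    n_b = params.background_rank

    if params.init_mode == "bare":
        b, f = nnmf(Y, n_b, seed=params.seed)
        resid = Y - b @ f
        A, C = greedy_roi(
            Movie(resid, prefix.fov_dims, prefix.frame_rate),
            InitParams(
                n_components=params.init_components,
                gaussian_width=params.neuron_radius,
                seed=params.seed,
            ),
        )
        for _ in range(3):
            C = hals_traces(Y - b @ f, A, C, n_passes=1)
            b = hals_footprints(Y - A @ C, b, f, n_passes=1)
            f = hals_traces(Y - A @ C, b, f, n_passes=1)
    elif params.init_mode == "batch":
        from caldemix.batch import BatchParams, run_batch

        bp = batch_params or BatchParams(seed=params.seed, frame_rate=prefix.frame_rate)
        comps, bg, _ = run_batch(prefix, bp)
        A, C = comps.footprints, comps.traces
        b, f = bg.spatial, bg.temporal
    else:
        if masks is None:
            raise ValueError("seeded init requires masks")
        from caldemix.initialization import seeded_initialization

        A, C, b, f = seeded_initialization(prefix, masks, background_rank=n_b, seed=params.seed)

    K = A.shape[1]
    cf = np.concatenate([C, f], axis=0)
    stat_yc = Y @ cf.T / t_prime
    stat_cc = cf @ cf.T / t_prime
    resid = Y - A @ C - b @ f
    buffer = resid[:, -l_b:].copy()

    T_alloc = total_frames if total_frames is not None else t_prime
    trace_history = np.zeros((K, T_alloc))
    trace_history[:, :t_prime] = C[:, :T_alloc] if t_prime > T_alloc else C
    bg_history = np.zeros((f.shape[0], T_alloc))
    bg_history[:, :t_prime] = f[:, :T_alloc] if t_prime > T_alloc else f

    q = np.power(2.0, np.arange(1, K + 1) / max(K, 1))
    return OnlineState(
        footprints=A,
        bg_spatial=b,
        trace_values=C[:, -1].copy() if K else np.zeros(0),
        bg_values=f[:, -1].copy() if f.size else np.zeros(f.shape[0]),
        stat_yc=stat_yc,
        stat_cc=stat_cc,
        residual_buffer=buffer,
        groups=_partition_groups(A),
        update_counter=q,
        t=t_prime,
        epoch=0,
        fov_dims=prefix.fov_dims,
        frame_rate=prefix.frame_rate,
        trace_history=trace_history,
        bg_history=bg_history,
        frame_index=t_prime,
    )


def find_new_components(
    residual_buffer: np.ndarray,
    fov_dims: tuple[int, int],
    n_candidates: int,
    neuron_radius: float,
    frame_rate: float,
    snr_threshold: float,
    classifier_threshold: float,
    classifier_model=None,
    transient_seconds: float = 0.4,
) -> tuple[np.ndarray, np.ndarray]:
    """Propose new components from the residual buffer.

    Local maxima (pairwise distance >= 2 * neuron_radius) of the spatially
    high-pass-filtered positive-residual energy image are screened on the
    mean residual crop — by the supplied classifier model, or by default
    by Pearson correlation against a centered Gaussian soma template
    (diffuse background leakage and noise correlate poorly with a compact
    radially symmetric bump) — and by the buffer-trace peak SNR; survivors
    are seeded by rank-1 NMF of the buffer restricted to a (2r+1)^2
    neighborhood.  Returns (A_new (d, k), C_new (k, l_b)).
    """
    rows, cols = fov_dims
    d, l_b = residual_buffer.shape
    empty = (np.zeros((d, 0)), np.zeros((0, l_b)))
    if n_candidates == 0:
        return empty
    r = max(int(round(neuron_radius)), 1)
    pos = np.maximum(residual_buffer, 0.0)
    energy = (pos**2).sum(axis=1).reshape(rows, cols)
    if energy.max() <= 0:
        return empty
    highpass = energy - ndimage.gaussian_filter(energy, sigma=2 * neuron_radius)
    peaks = peak_local_max(
        highpass, min_distance=2 * r, num_peaks=n_candidates, exclude_border=r
    )
    if peaks.size == 0:
        return empty
    mean_res = residual_buffer.mean(axis=1).reshape(rows, cols)

    new_a, new_c = [], []
    n_s = min(max(int(np.ceil(transient_seconds * frame_rate)), 1), l_b)
    sigma = neuron_radius / 2.0
    for pr, pc in peaks:
        if highpass[pr, pc] <= 0:
            continue
        r0, r1 = max(0, pr - r), min(rows, pr + r + 1)
        c0, c1 = max(0, pc - r), min(cols, pc + r + 1)
        crop = mean_res[r0:r1, c0:c1]
        if crop.max() <= 0:
            continue
        if classifier_model is not None:
            pos_crop = np.maximum(crop, 0.0)
            score = float(classify_footprints(pos_crop / pos_crop.max(), model=classifier_model)[0])
        else:
            rr_t, cc_t = np.mgrid[r0:r1, c0:c1]
            template = np.exp(-((rr_t - pr) ** 2 + (cc_t - pc) ** 2) / (2 * sigma**2))
            x, y_t = crop.ravel(), template.ravel()
            if np.std(x) == 0:
                continue
            score = float(np.corrcoef(x, y_t)[0, 1])
        if score < classifier_threshold:
            continue
        box_pix = (np.arange(r0, r1)[:, None] * cols + np.arange(c0, c1)[None, :]).ravel()
        patch = residual_buffer[box_pix]
        a_loc, c_buf = rank1_nmf(patch, n_iter=10, init_c=np.maximum(patch.mean(axis=0), 0))
        if a_loc.max() <= 0 or c_buf.max() <= 0:
            continue
        try:
            snr = peak_snr(c_buf, frame_rate, transient_seconds=n_s / frame_rate)
        except ValueError:
            continue
        if snr < snr_threshold:
            continue
        a = np.zeros(d)
        a[box_pix] = a_loc
        new_a.append(a)
        new_c.append(c_buf)
    if not new_a:
        return empty
    return np.stack(new_a, axis=1), np.stack(new_c, axis=0)


def _integrate_new_components(state: OnlineState, A_new: np.ndarray, C_new: np.ndarray) -> list[int]:
    """Append detected components with zero past history; expand the
    sufficient statistics with zero rows/columns and repartition groups."""
    k_new = A_new.shape[1]
    K_old = state.n_components
    n_b = state.bg_spatial.shape[1]
    # remove the new components' activity from the residual buffer so the
    # same transient is not proposed again on subsequent frames
    state.residual_buffer = state.residual_buffer - A_new @ C_new
    state.footprints = np.concatenate([state.footprints, A_new], axis=1)
    state.trace_values = np.concatenate([state.trace_values, C_new[:, -1]])
    state.trace_history = np.vstack(
        [state.trace_history, np.zeros((k_new, state.trace_history.shape[1]))]
    )
    # statistics gain zero history for the new components
    K_tot = K_old + k_new + n_b
    stat_yc = np.zeros((state.stat_yc.shape[0], K_tot))
    stat_cc = np.zeros((K_tot, K_tot))
    old_idx = list(range(K_old)) + list(range(K_old + k_new, K_tot))
    stat_yc[:, old_idx] = state.stat_yc
    stat_cc[np.ix_(old_idx, old_idx)] = state.stat_cc
    state.stat_yc, state.stat_cc = stat_yc, stat_cc
    state.update_counter = np.concatenate([state.update_counter, np.zeros(k_new)])
    state.groups = _partition_groups(state.footprints)
    new_indices = list(range(K_old, K_old + k_new))
    state.new_component_log.extend((state.t, i) for i in new_indices)
    return new_indices


def process_frame(
    state: OnlineState,
    frame: np.ndarray,
    params: OnlineParams,
    classifier_model=None,
    detect: bool = True,
) -> OnlineState:
    """Advance the streaming state by one frame (mutates ``state``)."""
    y = np.asarray(frame, dtype=float).ravel()
    if y.size != state.footprints.shape[0]:
        raise ValueError("frame does not match the FOV")
    if not np.isfinite(y).all():
        raise ValueError("frame contains non-finite values")

    A, b = state.footprints, state.bg_spatial
    K, n_b = state.n_components, b.shape[1]
    c = state.trace_values
    f = state.bg_values

    # --- trace update: block-coordinate descent over groups -------------
    a_norms = np.sum(A * A, axis=0)
    b_norms = np.sum(b * b, axis=0)
    resid = y - A @ c - (b @ f if n_b else 0.0)
    for _ in range(params.trace_passes):
        for g in state.groups:
            active = g[a_norms[g] > 0]
            if active.size == 0:
                continue
            step = (A[:, active].T @ resid) / a_norms[active]
            new = np.maximum(c[active] + step, 0.0)
            resid = resid - A[:, active] @ (new - c[active])
            c[active] = new
        for k in range(n_b):
            if b_norms[k] == 0:
                continue
            step = float(b[:, k] @ resid) / b_norms[k]
            new = max(f[k] + step, 0.0)
            resid = resid - b[:, k] * (new - f[k])
            f[k] = new

    # --- new-component detection ----------------------------------------
    newly_added: list[int] = []
    if detect and params.candidates_per_frame > 0:
        A_new, C_new = find_new_components(
            state.residual_buffer,
            state.fov_dims,
            params.candidates_per_frame,
            params.neuron_radius,
            state.frame_rate,
            params.snr_threshold,
            params.classifier_threshold,
            classifier_model=classifier_model,
            transient_seconds=params.transient_seconds,
        )
        if A_new.shape[1]:
            # the 2r separation rule also holds against existing
            # components: leftover residual shells around an imperfect fit
            # must not spawn satellite components
            keep = []
            cols = state.fov_dims[1]
            min_sep = 2.0 * params.neuron_radius
            if K:
                exist_pk = np.asarray(np.unravel_index(A.argmax(axis=0), state.fov_dims)).T
            for k_idx in range(A_new.shape[1]):
                a_cand = A_new[:, k_idx] / np.linalg.norm(A_new[:, k_idx])
                if K:
                    sims = (A.T @ a_cand) / np.maximum(np.sqrt(a_norms), 1e-12)
                    if sims.max() > 0.3:
                        continue
                    pk = np.unravel_index(int(A_new[:, k_idx].argmax()), state.fov_dims)
                    dists = np.hypot(exist_pk[:, 0] - pk[0], exist_pk[:, 1] - pk[1])
                    if dists.min() < min_sep:
                        continue
                keep.append(k_idx)
            A_new, C_new = A_new[:, keep], C_new[keep]
        if A_new.shape[1]:
            newly_added = _integrate_new_components(state, A_new, C_new)
            A, b = state.footprints, state.bg_spatial
            c = state.trace_values
            K = state.n_components
            resid = y - A @ c - (b @ f if n_b else 0.0)

    # --- residual buffer and sufficient statistics ----------------------
    state.residual_buffer = np.concatenate(
        [state.residual_buffer[:, 1:], resid[:, None]], axis=1
    )
    cf = np.concatenate([c, f])
    t_new = state.t + 1
    state.stat_yc *= state.t / t_new
    state.stat_yc += np.outer(y, cf) / t_new
    state.stat_cc *= state.t / t_new
    state.stat_cc += np.outer(cf, cf) / t_new
    state.t = t_new

    # --- scheduled shape updates ----------------------------------------
    due, state.update_counter = shape_update_schedule(
        state.update_counter, A, newly_added, params.shape_update_period
    )
    if due.size:
        K_now = state.n_components
        idx = np.concatenate([due, K_now + np.arange(n_b)]) if n_b else due
        state.footprints = update_shapes(
            state.stat_yc, state.stat_cc, A, b, idx, state.fov_dims
        )

    # --- record history ---------------------------------------------------
    if state.frame_index < state.trace_history.shape[1]:
        state.trace_history[:, state.frame_index] = c
        if n_b:
            state.bg_history[:, state.frame_index] = f
    state.frame_index += 1
    return state


def run_online(
    movie_source: str | Movie,
    params: OnlineParams | None = None,
    classifier_model=None,
    masks: np.ndarray | None = None,
    batch_params=None,
) -> tuple[ComponentSet, BackgroundModel, dict]:
    """Run the full streaming pipeline over a movie for the requested
    number of epochs and return the final components, background and a
    per-stage timing log.  Replayed epochs keep detection enabled and
    overwrite the recorded traces, back-filling components detected late.
    """
    params = params or OnlineParams()
    movie = load_movie(movie_source) if isinstance(movie_source, str) else movie_source
    T = movie.n_frames
    t0 = min(params.init_frames, T)
    prefix = Movie(movie.data[:, :t0].copy(), movie.fov_dims, movie.frame_rate)

    timing: dict[str, float] = {"init": 0.0, "stream": 0.0, "finalize": 0.0}
    tic = time.perf_counter()
    state = initialize_online(prefix, params, masks=masks, batch_params=batch_params, total_frames=T)
    timing["init"] = time.perf_counter() - tic

    tic = time.perf_counter()
    for epoch in range(params.epochs):
        state.epoch = epoch
        start = t0 if epoch == 0 else 0
        state.frame_index = start
        for t in range(start, T):
            process_frame(state, movie.frame(t), params, classifier_model=classifier_model)
    timing["stream"] = time.perf_counter() - tic

    tic = time.perf_counter()
    A = state.footprints
    C = state.trace_history
    keep = np.flatnonzero(A.sum(axis=0) > 0)
    A, C = A[:, keep], C[keep]
    comps = ComponentSet(A, C)
    if comps.n_components > 1:
        snrs = np.zeros(comps.n_components)
        for i in range(comps.n_components):
            try:
                snrs[i] = peak_snr(C[i], movie.frame_rate)
            except ValueError:
                snrs[i] = 0.0
        kept = detect_duplicates(comps, snrs, overlap_dup=0.7)
        comps = comps.select(kept)
    if comps.n_components:
        S = np.zeros_like(comps.traces)
        den = np.zeros_like(comps.traces)
        for i in range(comps.n_components):
            den[i], S[i] = oasis_deconvolve(comps.traces[i], DeconvParams())
        comps = ComponentSet(comps.footprints, comps.traces, deconvolved=S)
    bg = BackgroundModel(kind="low_rank", spatial=state.bg_spatial, temporal=state.bg_history)
    timing["finalize"] = time.perf_counter() - tic
    return comps, bg, timing
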