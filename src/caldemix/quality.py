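"""Component quality assessment.

Three tests decide whether an extracted component corresponds to an active
neuron:

1. *Spatial consistency* — around the component's strongest transients the
   background- and neighbor-subtracted data, averaged in time, should look
   like the component's own footprint (Pearson correlation over a local
   box).
2. *Trace peak-SNR* — the z-scored trace's most unlikely positive
   excursion over a transient-length window, expressed in Gaussian
   standard deviations: the probability of each window is the geometric
   mean of per-frame upper-tail probabilities, and the SNR is the probit
   of the minimal window probability.  Computed in the log domain for
   numerical stability.
3. *Footprint shape* — a classifier score in [0, 1] for how much the
   footprint resembles a neural soma.  The default scorer is a
   deterministic geometric one (compactness x solidity of the thresholded
   crop); an optional learned classifier trained on synthetic crops can be
   supplied instead.

The noise level entering the z-score is estimated from sub-baseline
samples as the scale of a half-normal distribution, which is immune to the
positive-only calcium transients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import log_ndtr, ndtri_exp
from scipy.stats import pearsonr
from skimage import measure, morphology, transform

from caldemix._baseline import percentile_baseline
from caldemix.model import BackgroundModel, ComponentSet
from caldemix.movies import Movie

__all__ = [
    "QualityThresholds",
    "QualityReport",
    "residual_trace",
    "residual_traces",
    "noise_level",
    "peak_snr",
    "spatial_consistency",
    "classify_footprints",
    "footprint_crop",
    "evaluate_components",
    "detect_duplicates",
]

_HALF_NORMAL_STD = float(np.sqrt(1.0 - 2.0 / np.pi))


@dataclass
class QualityThresholds:
    """Acceptance thresholds and windowing for the three tests.

    ``peak_window`` is (past_ms, future_ms) around each trace peak used by
    the spatial-consistency average; ``transient_seconds`` sets the
    peak-SNR window length N_s = ceil(transient_seconds * frame_rate).
    """

    space_corr_min: float = 0.5
    snr_min: float = 2.0
    classifier_accept: float = 0.5
    classifier_reject_floor: float = 0.1
    overlap_dup: float = 0.7
    n_peaks: int = 5
    peak_window: tuple[float, float] = (50.0, 300.0)
    transient_seconds: float = 0.4
    use_classifier: bool = True
    snr_override: bool = False  # classifier_accept may rescue a marginal SNR failure
    # expected neuron radius in pixels; when set, classifier crops use a
    # fixed box of half-size 2x this radius, preserving the size cue that
    # separates soma-sized footprints from diffuse background blobs
    neuron_radius: float | None = None

    def __post_init__(self) -> None:
        for name in ("space_corr_min", "classifier_accept", "classifier_reject_floor"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0 < self.overlap_dup <= 1):
            raise ValueError("overlap_dup must lie in (0, 1]")


@dataclass
class QualityReport:
    """Per-component raw test values and the combined decision."""

    space_correlation: np.ndarray
    snr: np.ndarray
    classifier_score: np.ndarray
    accepted: np.ndarray
    rejection_reasons: list[list[str]] = field(default_factory=list)

    @property
    def accepted_indices(self) -> np.ndarray:
        return np.flatnonzero(self.accepted)


def residual_traces(
    movie: Movie, components: ComponentSet, background: BackgroundModel | None
) -> np.ndarray:
    """All component residual traces r_i = R' a_i / ||a_i||^2 with
    R = Y - A C - B, stacked as (N, T)."""
    Y = movie.data
    R = Y - components.reconstruct()
    if background is not None:
        R = R - background.matrix(Y, components)
    A = components.footprints
    norms = np.sum(A * A, axis=0)
    if np.any(norms == 0):
        raise ValueError("zero footprint has no residual trace")
    return (A.T @ R) / norms[:, None]


def residual_trace(
    movie: Movie, components: ComponentSet, background: BackgroundModel | None, i: int
) -> np.ndarray:
    """Residual trace of component i (see :func:`residual_traces`)."""
    a = components.footprints[:, i]
    norm2 = float(a @ a)
    if norm2 == 0:
        raise ValueError(f"component {i} has a zero footprint")
    Y = movie.data
    R = Y - components.reconstruct()
    if background is not None:
        R = R - background.matrix(Y, components)
    return (R.T @ a) / norm2


def noise_level(
    trace: np.ndarray,
    frame_rate: float = 30.0,
    baseline: np.ndarray | None = None,
) -> float:
    """Noise level of a trace from its sub-baseline samples.

    Calcium transients are positive-only, so samples at or below the
    baseline are pure noise; their spread is the scale of a half-normal
    distribution, std(sub-baseline) / sqrt(1 - 2/pi).  The half-normal
    formula assumes the split point is the center of the noise
    distribution, so when no baseline is supplied the running median is
    used (for sparse-activity traces it sits in the resting part).
    """
    y = np.asarray(trace, dtype=float).ravel()
    if baseline is None:
        baseline = percentile_baseline(y, frame_rate, percentile=50)
    dev = y - baseline
    sub = dev[dev <= 0]
    if sub.size < 10:
        raise ValueError(
            f"only {sub.size} sub-baseline samples; trace too short or degenerate for a noise estimate"
        )
    return float(np.std(sub) / _HALF_NORMAL_STD)


def peak_snr(
    trace: np.ndarray,
    frame_rate: float = 30.0,
    transient_seconds: float = 0.4,
    noise: float | None = None,
    baseline: np.ndarray | None = None,
) -> float:
    """Windowed peak-SNR of a trace.

    z-scores the trace against its baseline and noise level, converts each
    frame to an upper-tail probability p(t) = Phi(-z(t)), takes the
    geometric mean over every full window of N_s = ceil(transient_seconds
    * frame_rate) frames, and returns the probit of the smallest window
    probability: SNR = -Phi^{-1}(p_min).  Windows truncated by the trace
    end are skipped.  Everything runs in the log domain.
    """
    y = np.asarray(trace, dtype=float).ravel()
    T = y.size
    n_s = int(np.ceil(transient_seconds * frame_rate))
    if n_s < 1 or n_s > T:
        raise ValueError(f"window of {n_s} frames does not fit a length-{T} trace")
    if baseline is None:
        baseline = percentile_baseline(y, frame_rate)
    if noise is None:
        noise = noise_level(y, frame_rate, baseline=baseline)
    if noise <= 0:
        raise ValueError("non-positive noise level")
    z = (y - baseline) / noise
    logp = log_ndtr(-z)
    window_means = np.convolve(logp, np.ones(n_s) / n_s, mode="valid")
    log_pmin = float(window_means.min())
    return float(-ndtri_exp(min(log_pmin, -1e-300)))


def _local_peaks(trace: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima (interior) of a 1-D trace."""
    y = np.asarray(trace, dtype=float)
    if y.size < 3:
        return np.array([], dtype=int)
    return np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])) + 1


def _footprint_geometry(a_img: np.ndarray, threshold: float = 0.2) -> tuple[np.ndarray, float]:
    """Centroid (row, col) and effective radius of a footprint image."""
    mask = a_img >= threshold * a_img.max()
    total = a_img.sum()
    rr, cc = np.nonzero(a_img > 0)
    if total <= 0 or rr.size == 0:
        raise ValueError("empty footprint")
    w = a_img[rr, cc] / total
    centroid = np.array([float(rr @ w), float(cc @ w)])
    radius = max(float(np.sqrt(mask.sum() / np.pi)), 1.0)
    return centroid, radius


def spatial_consistency(
    movie: Movie,
    components: ComponentSet,
    background: BackgroundModel | None,
    i: int,
    thresholds: QualityThresholds | None = None,
    z_scores: np.ndarray | None = None,
    background_matrix: np.ndarray | None = None,
) -> tuple[float, str | None]:
    """Correlation between footprint i and the data averaged around its
    strongest transients.

    Builds Y_i = Y - A_{\\i} C_{\\i} - B, averages it over the union of
    windows [peak - past, peak + future] around the top-``n_peaks`` local
    peaks of c_i, and returns the Pearson correlation between that average
    image and a_i, both restricted to a box of side 4 x (footprint radius)
    around the footprint centroid.  Peaks during which a spatially
    overlapping component is strongly active (z > 2) are skipped so that a
    neighbor's transients cannot vouch for this footprint.

    Returns ``(correlation, reason)`` where ``reason`` is "no activity"
    (and the correlation 0) for a trace without local peaks.
    """
    thresholds = thresholds or QualityThresholds()
    A, C = components.footprints, components.traces
    c_i = C[i]
    peaks = _local_peaks(c_i)
    if peaks.size == 0:
        return 0.0, "no activity"

    # Exclude peaks contaminated by active spatial neighbors.
    overlapping = [
        j for j in range(components.n_components) if j != i and float(A[:, j] @ A[:, i]) > 0
    ]
    if overlapping:
        if z_scores is None:
            z_scores = np.zeros_like(C)
            for j in overlapping:
                c_j = C[j]
                try:
                    sigma_j = noise_level(c_j, movie.frame_rate)
                except ValueError:
                    continue
                base_j = percentile_baseline(c_j, movie.frame_rate)
                z_scores[j] = (c_j - base_j) / sigma_j
        good = [p for p in peaks if not any(z_scores[j, p] > 2.0 for j in overlapping)]
        if good:
            peaks = np.asarray(good)

    order = np.argsort(c_i[peaks])[::-1]
    peaks = peaks[order][: thresholds.n_peaks]

    F = movie.frame_rate
    past = int(round(thresholds.peak_window[0] / 1000.0 * F))
    future = int(round(thresholds.peak_window[1] / 1000.0 * F))
    T = movie.n_frames
    frames: set[int] = set()
    for p in peaks:
        frames.update(range(max(0, p - past), min(T, p + future + 1)))
    frame_idx = np.array(sorted(frames), dtype=int)

    Y_i = movie.data[:, frame_idx] - np.delete(A, i, axis=1) @ np.delete(C, i, axis=0)[:, frame_idx]
    if background_matrix is not None:
        Y_i = Y_i - background_matrix[:, frame_idx]
    elif background is not None:
        B = background.matrix(movie.data, components)
        Y_i = Y_i - B[:, frame_idx]
    mean_img = Y_i.mean(axis=1).reshape(movie.fov_dims)

    a_img = A[:, i].reshape(movie.fov_dims)
    centroid, radius = _footprint_geometry(a_img)
    half = max(int(np.ceil(2 * radius)), 2)
    r0 = max(0, int(round(centroid[0])) - half)
    r1 = min(movie.fov_dims[0], int(round(centroid[0])) + half + 1)
    c0 = max(0, int(round(centroid[1])) - half)
    c1 = min(movie.fov_dims[1], int(round(centroid[1])) + half + 1)

    x = mean_img[r0:r1, c0:c1].ravel()
    y = a_img[r0:r1, c0:c1].ravel()
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0, "degenerate box"
    return float(pearsonr(x, y).statistic), None


def footprint_crop(
    footprint: np.ndarray,
    fov_dims: tuple[int, int],
    side: int = 50,
    radius: float | None = None,
) -> np.ndarray:
    """Max-normalized square crop around a footprint's centroid, resampled
    to ``side`` x ``side`` for the classifier.  With ``radius`` given the
    crop box is fixed at 2x that radius regardless of the footprint's own
    extent, so oversized footprints fill their crop."""
    a_img = footprint.reshape(fov_dims)
    centroid, own_radius = _footprint_geometry(a_img)
    half = max(int(np.ceil(2 * (radius if radius is not None else own_radius))), 4)
    r0 = max(0, int(round(centroid[0])) - half)
    r1 = min(fov_dims[0], int(round(centroid[0])) + half + 1)
    c0 = max(0, int(round(centroid[1])) - half)
    c1 = min(fov_dims[1], int(round(centroid[1])) + half + 1)
    crop = a_img[r0:r1, c0:c1]
    crop = transform.resize(crop, (side, side), order=1, anti_aliasing=True)
    peak = crop.max()
    return crop / peak if peak > 0 else crop


def _geometric_score(crop: np.ndarray) -> float:
    """Deterministic soma-likeness score: geometric mean of compactness
    (4 pi A / P^2) and solidity of the half-max thresholded crop, weighted
    by how much of the mask its largest connected piece holds.  Compact
    blob-like footprints score near 1; scattered or elongated shapes score
    low."""
    peak = crop.max()
    if peak <= 0:
        return 0.0
    mask = crop >= 0.5 * peak
    if mask.sum() < 4:
        return 0.0
    labels = measure.label(mask, connectivity=1)
    sizes = np.bincount(labels.ravel())[1:]
    cc_frac = float(sizes.max() / mask.sum())
    area = float(mask.sum())
    perim = float(measure.perimeter(mask, neighborhood=4))
    compactness = min(4.0 * np.pi * area / perim**2, 1.0) if perim > 0 else 1.0
    hull = morphology.convex_hull_image(mask)
    solidity = area / float(hull.sum())
    score = float(np.sqrt(compactness * solidity) * cc_frac)
    # soma-size prior: a soma occupies a small central fraction of its
    # crop; a mask filling the crop is diffuse background, however compact
    # it looks, and is cut off decisively
    fill = area / mask.size
    if fill > 0.3:
        score *= max(0.0, (0.45 - fill) / 0.15)
    return score


def classify_footprints(crops: np.ndarray, model=None) -> np.ndarray:
    """Score footprint crops in [0, 1] for soma-likeness.

    ``crops`` is a stack (n, h, w); each crop is max-normalized and
    resampled to the model's input side.  With ``model=None`` the
    deterministic geometric scorer is used; otherwise ``model`` must
    expose ``score_crops(crops) -> scores`` (see
    :mod:`caldemix.classifier`).
    """
    crops = np.asarray(crops, dtype=float)
    if crops.ndim == 2:
        crops = crops[None]
    if model is not None:
        return np.asarray(model.score_crops(crops), dtype=float)
    out = np.empty(crops.shape[0])
    for k, crop in enumerate(crops):
        peak = crop.max()
        norm = crop / peak if peak > 0 else crop
        if norm.shape != (50, 50):
            norm = transform.resize(norm, (50, 50), order=1, anti_aliasing=True)
        out[k] = _geometric_score(norm)
    return out


def evaluate_components(
    movie: Movie,
    components: ComponentSet,
    background: BackgroundModel | None,
    thresholds: QualityThresholds | None = None,
    classifier_model=None,
) -> QualityReport:
    """Run the three quality tests on every component.

    A component is accepted iff its spatial consistency, peak-SNR and
    classifier score all pass; with ``snr_override`` on, a classifier
    score above ``classifier_accept`` rescues a marginal SNR failure.
    """
    thresholds = thresholds or QualityThresholds()
    N = components.n_components
    T = movie.n_frames
    space = np.zeros(N)
    snr = np.zeros(N)
    scores = np.ones(N)
    accepted = np.zeros(N, dtype=bool)
    reasons: list[list[str]] = []
    if N == 0:
        return QualityReport(space, snr, scores, accepted, reasons)

    res = residual_traces(movie, components, background)
    if thresholds.use_classifier:
        crops = np.stack(
            [
                footprint_crop(
                    components.footprints[:, i], movie.fov_dims, radius=thresholds.neuron_radius
                )
                for i in range(N)
            ]
        )
        scores = classify_footprints(crops, model=classifier_model)

    # one pass of baselines / noise levels / z-scores shared by all tests
    traces_nd = components.traces + res
    z = np.zeros((N, T))
    noises = np.zeros(N)
    baselines = np.zeros((N, T))
    for i in range(N):
        baselines[i] = percentile_baseline(traces_nd[i], movie.frame_rate)
        try:
            noises[i] = noise_level(traces_nd[i], movie.frame_rate, baseline=baselines[i])
        except ValueError:
            noises[i] = 0.0
        if noises[i] > 0:
            z[i] = (traces_nd[i] - baselines[i]) / noises[i]
    B = background.matrix(movie.data, components) if background is not None else None

    for i in range(N):
        why: list[str] = []
        try:
            snr[i] = peak_snr(
                traces_nd[i],
                movie.frame_rate,
                transient_seconds=min(thresholds.transient_seconds, T / movie.frame_rate),
                noise=noises[i] if noises[i] > 0 else None,
                baseline=baselines[i],
            )
        except ValueError:
            snr[i] = 0.0
        space[i], reason = spatial_consistency(
            movie, components, background, i, thresholds, z_scores=z, background_matrix=B
        )
        if reason == "no activity":
            why.append("no activity")

        ok_space = space[i] >= thresholds.space_corr_min
        ok_snr = snr[i] >= thresholds.snr_min
        ok_cls = (not thresholds.use_classifier) or scores[i] >= thresholds.classifier_reject_floor
        if thresholds.use_classifier and thresholds.snr_override and not ok_snr:
            ok_snr = scores[i] >= thresholds.classifier_accept
        if not ok_space:
            why.append("space_corr")
        if not ok_snr:
            why.append("snr")
        if not ok_cls:
            why.append("classifier")
        accepted[i] = ok_space and ok_snr and ok_cls
        reasons.append(why)
    return QualityReport(space, snr, scores, accepted, reasons)


def detect_duplicates(
    components: ComponentSet | np.ndarray,
    scores: np.ndarray,
    overlap_dup: float = 0.7,
    binarize_threshold: float = 0.2,
) -> np.ndarray:
    """Remove near-duplicate footprints.

    The overlap O_ij = |m_i n m_j| / |m_j| (i != j, O_ii = 0) measures the
    fraction of component j's binarized mask covered by component i's.  As
    long as any entry exceeds ``overlap_dup`` the lower-scoring member of
    the worst pair is removed (ties keep the lower index).  Returns the
    kept indices, whose pairwise overlaps are all at or below threshold by
    construction.
    """
    A = components.footprints if isinstance(components, ComponentSet) else components
    scores = np.asarray(scores, dtype=float)
    N = A.shape[1]
    if scores.shape != (N,):
        raise ValueError("one score per component required")
    masks = np.empty((N, A.shape[0]), dtype=bool)
    for i in range(N):
        col = A[:, i]
        if col.max() <= 0:
            raise ValueError(f"component {i} has an empty footprint")
        masks[i] = col >= binarize_threshold * col.max()
    sizes = masks.sum(axis=1).astype(float)

    kept = list(range(N))
    while True:
        M = masks[kept].astype(float)
        inter = M @ M.T
        O = inter / sizes[kept][None, :]
        np.fill_diagonal(O, 0.0)
        if O.max() <= overlap_dup:
            break
        i_loc, j_loc = np.unravel_index(np.argmax(O), O.shape)
        pair = (kept[i_loc], kept[j_loc])
        if scores[pair[0]] == scores[pair[1]]:
            drop = max(pair)
        else:
            drop = pair[0] if scores[pair[0]] < scores[pair[1]] else pair[1]
        kept.remove(drop)
    return np.asarray(kept, dtype=int)
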