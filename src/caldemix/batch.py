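"""Batch source extraction: patch-parallel constrained NMF.

The movie is tiled into overlapping spatial patches (accessed cheaply
through the pixel-major memmap), each patch is factored independently
(initialize, alternate HALS updates, quality-filter), and the per-patch
results are recombined: footprints are embedded at their patch offsets and
normalized by how many patches cover each pixel, duplicates straddling
patch seams are merged into single rank-1 components, and patch
backgrounds are compressed into one low-rank model.  A final full-FOV HALS
refinement polishes the combined estimate.

For one-photon microendoscopic data the low-rank background underfits the
large diffuse signal; the ring model expresses each pixel's background as
a nonnegative combination of the residual traces on an annulus around it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, sparse
from scipy.optimize import nnls
from scipy.sparse.csgraph import connected_components as _graph_components

import h5py
import yaml

from caldemix._nmf import hals_footprints, hals_traces, nnmf, rank1_nmf
from caldemix.deconvolution import DeconvParams, oasis_deconvolve
from caldemix.initialization import InitParams, initialize
from caldemix.model import BackgroundModel, ComponentSet
from caldemix.movies import MemmapMovie, Movie, load_movie, open_memmap, read_patch, write_memmap
from caldemix.quality import QualityReport, QualityThresholds, detect_duplicates, evaluate_components

__all__ = [
    "PatchLayout",
    "BatchParams",
    "construct_patches",
    "process_in_patches",
    "merge_components",
    "merge_backgrounds",
    "hals_refine",
    "ring_background",
    "run_batch",
    "ComponentSet",
    "BackgroundModel",
]

logger = logging.getLogger(__name__)


@dataclass
class PatchLayout:
    """Tiling of the FOV into overlapping half-open pixel ranges."""

    fov_dims: tuple[int, int]
    patch_size: tuple[int, int]
    overlap: int
    patches: list[tuple[tuple[int, int], tuple[int, int]]]
    coverage: np.ndarray  # (rows, cols) patch count per pixel

    @property
    def n_patches(self) -> int:
        return len(self.patches)


@dataclass
class BatchParams:
    """End-to-end batch pipeline settings.

    Defaults are sized to desk-scale synthetic movies (64 x 64 x 1000
    frames, ~20 neurons).
    """

    patch_size: tuple[int, int] = (48, 48)
    overlap: int = 8
    components_per_patch: int = 12
    background_rank: int = 2
    merge_threshold: float = 0.8
    merged_background_rank: int = 1  # g_b: per-patch background compression rank
    hals_iterations: int = 5
    final_hals_iterations: int = 5
    init: InitParams = field(default_factory=InitParams)
    # batch acceptance settings: SNR 2, spatial consistency 0.75,
    # classifier floor 0.1; the shape classifier carries the burden of
    # rejecting diffuse background components
    quality: QualityThresholds = field(
        default_factory=lambda: QualityThresholds(space_corr_min=0.75)
    )
    mode: str = "2p"  # "2p" low-rank background, "1p" ring background
    ring_radius: float | None = None  # default 2x neuron radius
    frame_rate: float = 30.0
    deconvolve: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.merge_threshold <= 1):
            raise ValueError("merge_threshold must lie in [0, 1]")
        if self.mode not in {"2p", "1p"}:
            raise ValueError("mode must be '2p' or '1p'")
        if self.quality.neuron_radius is None:
            self.quality.neuron_radius = self.init.gaussian_width


_classifier_cache: dict[int, object] = {}


def default_classifier(seed: int = 0):
    """Process-wide cached footprint classifier trained on synthetic
    crops with a fixed seed (so repeated runs are deterministic)."""
    if seed not in _classifier_cache:
        from caldemix.classifier import train_footprint_classifier

        _classifier_cache[seed] = train_footprint_classifier(seed=seed)
    return _classifier_cache[seed]


def _axis_starts(dim: int, patch: int, stride: int, overlap: int) -> list[int]:
    starts = [0]
    s = stride
    while s + overlap < dim and s < dim:
        starts.append(s)
        s += stride
    return starts


def construct_patches(
    fov_dims: tuple[int, int], patch_size: tuple[int, int], overlap: int
) -> PatchLayout:
    """Tile the FOV with stride ``patch_size - overlap``; the final patch
    of each axis is clamped at the border.  Every pixel is covered at
    least once and interior seams exactly ``overlap`` pixels wide."""
    rows, cols = fov_dims
    pr, pc = min(patch_size[0], rows), min(patch_size[1], cols)
    if overlap >= pr or overlap >= pc:
        raise ValueError(f"overlap {overlap} must be smaller than the patch size {patch_size}")
    row_starts = _axis_starts(rows, pr, pr - overlap, overlap)
    col_starts = _axis_starts(cols, pc, pc - overlap, overlap)
    patches = []
    coverage = np.zeros(fov_dims, dtype=int)
    for r0 in row_starts:
        for c0 in col_starts:
            r1, c1 = min(r0 + pr, rows), min(c0 + pc, cols)
            patches.append(((r0, r1), (c0, c1)))
            coverage[r0:r1, c0:c1] += 1
    return PatchLayout(fov_dims, (pr, pc), overlap, patches, coverage)


def merge_components(components: ComponentSet, merge_threshold: float = 0.8) -> ComponentSet:
    """Replace groups of spatially overlapping, temporally correlated
    components by single rank-1 components.

    Components i, j belong to one group when a_i' a_j > 0 and
    corr(c_i, c_j) >= ``merge_threshold`` (connected closure).  Each group
    is replaced by the nonnegative rank-1 pair (a_m, c_m) minimizing
    ||A_old C_old - a_m c_m'|| over the group, fit by alternating updates
    initialized from the largest-energy member.  Never increases the
    component count.
    """
    N = components.n_components
    if N <= 1:
        return components
    A, C = components.footprints, components.traces
    overlap = (A.T @ A) > 0
    Cc = C - C.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Cc, axis=1)
    norms[norms == 0] = 1.0
    corr = (Cc @ Cc.T) / np.outer(norms, norms)
    adj = overlap & (corr >= merge_threshold)
    np.fill_diagonal(adj, False)
    n_groups, labels = _graph_components(sparse.csr_matrix(adj), directed=False)

    out_A, out_C = [], []
    for g in range(n_groups):
        members = np.flatnonzero(labels == g)
        if members.size == 1:
            i = members[0]
            out_A.append(A[:, i])
            out_C.append(C[i])
            continue
        sub_A, sub_C = A[:, members], C[members]
        rows_used = np.flatnonzero(np.abs(sub_A).sum(axis=1) > 0)
        prod = sub_A[rows_used] @ sub_C
        energies = np.linalg.norm(sub_A, axis=0) * np.linalg.norm(sub_C, axis=1)
        lead = int(np.argmax(energies))
        a_loc, c = rank1_nmf(prod, n_iter=50, tol=0.0, init_c=np.maximum(sub_C[lead], 0))
        a = np.zeros(A.shape[0])
        a[rows_used] = a_loc
        out_A.append(a)
        out_C.append(c)
    # groups are labeled by ascending smallest member, preserving order
    merged = ComponentSet(np.stack(out_A, axis=1), np.stack(out_C, axis=0))
    return merged.drop_empty()


def merge_backgrounds(
    patch_backgrounds: list[tuple[np.ndarray, np.ndarray, tuple[tuple[int, int], tuple[int, int]]]],
    fov_dims: tuple[int, int],
    n_frames: int,
    g_b: int = 1,
    final_rank: int = 2,
    coverage: np.ndarray | None = None,
    seed: int = 0,
) -> BackgroundModel:
    """Combine per-patch low-rank backgrounds into one full-FOV model.

    Each patch background B_i is approximated by rank-``g_b`` NMF, its
    spatial modes embedded at the patch offset (normalized by patch
    coverage where patches overlap); the collection is compressed by a
    final rank-``final_rank`` NMF pass when it exceeds that rank.
    """
    d = fov_dims[0] * fov_dims[1]
    spatial_cols, temporal_rows = [], []
    for b_i, f_i, ((r0, r1), (c0, c1)) in patch_backgrounds:
        if b_i.size == 0 or f_i.size == 0:
            continue
        B_i = b_i @ f_i
        if not np.any(B_i):
            continue
        if b_i.shape[1] <= g_b:  # already in rank-g_b factored form
            w, h = b_i, f_i
        else:
            w, h = nnmf(B_i, min(g_b, min(B_i.shape)), seed=seed)
        box_pix = (np.arange(r0, r1)[:, None] * fov_dims[1] + np.arange(c0, c1)[None, :]).ravel()
        for k in range(w.shape[1]):
            col = np.zeros(d)
            col[box_pix] = w[:, k]
            spatial_cols.append(col)
            temporal_rows.append(h[k])
    if not spatial_cols:
        return BackgroundModel.empty(d, n_frames)
    b = np.stack(spatial_cols, axis=1)
    f = np.stack(temporal_rows, axis=0)
    if coverage is not None:
        b = b / coverage.ravel()[:, None].clip(min=1)
    if b.shape[1] > final_rank:
        b, f = nnmf(b @ f, final_rank, seed=seed)
    return BackgroundModel(kind="low_rank", spatial=b, temporal=f)


def hals_refine(
    movie: Movie,
    components: ComponentSet,
    background: BackgroundModel,
    iterations: int = 5,
    support_dilation: int = 1,
) -> tuple[ComponentSet, BackgroundModel]:
    """Alternating nonnegative refinement of (A, C, b, f).

    Footprint updates are confined to the current nonzero support dilated
    by ``support_dilation`` pixels, letting footprints grow slowly without
    losing locality.  Every blockwise update is an exact coordinate
    minimization, so the Frobenius objective ||Y - A C - b f||_F is
    non-increasing; an increase beyond numerical tolerance aborts with
    diagnostics.
    """
    if iterations == 0:
        return components, background
    if background.kind != "low_rank":
        raise ValueError("hals_refine expects a low-rank background; see ring_background")
    Y = movie.data
    A = components.footprints.copy()
    C = components.traces.copy()
    b = background.spatial.copy()
    f = background.temporal.copy()

    support = _dilated_support(A, movie.fov_dims, support_dilation)

    def objective() -> float:
        return float(np.linalg.norm(Y - A @ C - b @ f, "fro"))

    prev = objective()
    for it in range(iterations):
        resid_bg = Y - A @ C
        b = hals_footprints(resid_bg, b, f, n_passes=1)
        f = hals_traces(resid_bg, b, f, n_passes=1)
        Yb = Y - b @ f
        C = hals_traces(Yb, A, C, n_passes=1)
        A = hals_footprints(Yb, A, C, support=support, n_passes=1)
        cur = objective()
        if cur > prev * (1 + 1e-8) + 1e-8:
            raise RuntimeError(
                f"HALS diverged at iteration {it}: objective {prev:.6g} -> {cur:.6g}"
            )
        prev = cur
    out = ComponentSet(A, C, deconvolved=components.deconvolved).drop_empty()
    return out, BackgroundModel(kind="low_rank", spatial=b, temporal=f)


def _dilated_support(A: np.ndarray, fov_dims: tuple[int, int], dilation: int) -> np.ndarray | None:
    if A.shape[1] == 0:
        return None
    support = np.zeros(A.shape, dtype=bool)
    structure = ndimage.generate_binary_structure(2, 2)
    for i in range(A.shape[1]):
        mask = (A[:, i] > 0).reshape(fov_dims)
        if dilation > 0:
            mask = ndimage.binary_dilation(mask, structure=structure, iterations=dilation)
        support[:, i] = mask.ravel()
    return support


def ring_background(
    movie: Movie,
    components: ComponentSet,
    ring_radius: float,
    ring_width: float = 1.0,
    max_regressors: int = 32,
) -> BackgroundModel:
    """One-photon ring background model.

    Each pixel's background trace is a nonnegative combination of the
    component-subtracted residual traces of pixels on an annulus
    [ring_radius, ring_radius + ring_width) around it, estimated row by
    row with nonnegative least squares; the annulus is subsampled to at
    most ``max_regressors`` pixels per row for tractability.
    """
    rows, cols = movie.fov_dims
    if ring_radius > np.hypot(rows - 1, cols - 1):
        raise ValueError(
            f"annulus at radius {ring_radius} lies outside the {rows}x{cols} FOV"
        )
    offsets = []
    r_hi = ring_radius + ring_width
    for dy in range(-int(np.ceil(r_hi)), int(np.ceil(r_hi)) + 1):
        for dx in range(-int(np.ceil(r_hi)), int(np.ceil(r_hi)) + 1):
            dist = np.hypot(dy, dx)
            if ring_radius <= dist < r_hi:
                offsets.append((dy, dx))
    if not offsets:
        raise ValueError(f"annulus [{ring_radius}, {r_hi}) contains no pixels")
    if len(offsets) > max_regressors:
        idx = np.linspace(0, len(offsets) - 1, max_regressors).astype(int)
        offsets = [offsets[k] for k in idx]

    X = movie.data - components.reconstruct()
    d = movie.n_pixels
    W_rows, W_cols, W_vals = [], [], []
    for p in range(d):
        py, px = divmod(p, cols)
        ring_pix = [
            (py + dy) * cols + (px + dx)
            for dy, dx in offsets
            if 0 <= py + dy < rows and 0 <= px + dx < cols
        ]
        if not ring_pix:
            continue
        G = X[ring_pix].T  # (T, k)
        if not np.any(G):
            continue
        w, _ = nnls(G, X[p])
        nz = np.flatnonzero(w > 0)
        W_rows.extend([p] * nz.size)
        W_cols.extend([ring_pix[k] for k in nz])
        W_vals.extend(w[nz])
    W = sparse.csr_matrix((W_vals, (W_rows, W_cols)), shape=(d, d))
    return BackgroundModel(kind="ring", ring_weights=W, ring_radius=ring_radius)


def _cnmf_single(movie: Movie, params: BatchParams) -> tuple[ComponentSet, BackgroundModel]:
    """Initialize + HALS on one in-memory movie (a patch or the full FOV)."""
    init = replace(
        params.init,
        n_components=min(params.components_per_patch, movie.n_pixels),
        background_rank=params.background_rank,
        seed=params.seed,
    )
    comps, bg = initialize(movie, init)
    comps = comps.drop_empty()
    if params.hals_iterations > 0:
        comps, bg = hals_refine(movie, comps, bg, iterations=params.hals_iterations)
    return comps, bg


def process_in_patches(
    movie: MemmapMovie,
    layout: PatchLayout,
    params: BatchParams,
    classifier_model=None,
) -> tuple[ComponentSet, BackgroundModel]:
    """Run CNMF independently on every patch and combine the results.

    Per-patch footprints are embedded at their offsets, every component's
    pixel values divided by the patch coverage count there (so signal in
    seam pixels is not counted twice), then seam duplicates are merged and
    patch backgrounds compressed into one low-rank model.  Patch results
    do not depend on processing order.
    """
    d = movie.n_pixels
    T = movie.n_frames
    cov = layout.coverage.ravel().astype(float)
    pieces: list[ComponentSet] = []
    patch_bgs = []
    for ((r0, r1), (c0, c1)) in layout.patches:
        data = np.asarray(read_patch(movie, (r0, r1), (c0, c1)), dtype=float)
        patch_movie = Movie(data, (r1 - r0, c1 - c0), movie.frame_rate)
        comps, bg = _cnmf_single(patch_movie, params)
        if comps.n_components > 0:
            # the shape test is deferred to the combined full-FOV pass:
            # footprints clipped at patch borders are legitimate halves of
            # seam-straddling neurons, not bad shapes
            patch_quality = replace(params.quality, use_classifier=False)
            report = evaluate_components(patch_movie, comps, bg, patch_quality)
            comps = comps.select(report.accepted_indices).drop_empty()
        box_pix = (np.arange(r0, r1)[:, None] * layout.fov_dims[1] + np.arange(c0, c1)[None, :]).ravel()
        if comps.n_components > 0:
            A_full = np.zeros((d, comps.n_components))
            A_full[box_pix] = comps.footprints / cov[box_pix][:, None]
            pieces.append(ComponentSet(A_full, comps.traces))
        patch_bgs.append((bg.spatial, bg.temporal, ((r0, r1), (c0, c1))))

    if pieces:
        combined = ComponentSet.concatenate(pieces)
        combined = merge_components(combined, params.merge_threshold)
    else:
        combined = ComponentSet.empty(d, T)
    background = merge_backgrounds(
        patch_bgs,
        layout.fov_dims,
        T,
        g_b=params.merged_background_rank,
        final_rank=params.background_rank,
        coverage=layout.coverage,
        seed=params.seed,
    )
    # full-FOV refinement before any quality assessment: repairs seam
    # artifacts (coverage-halved strips, footprints clipped by a patch
    # border) that merging alone cannot fix
    if params.hals_iterations > 0 and combined.n_components > 0:
        combined, background = hals_refine(
            movie.to_movie(), combined, background, iterations=params.hals_iterations
        )
        A = _keep_main_blob(combined.footprints, layout.fov_dims)
        full = movie.to_movie()
        C = hals_traces(full.data - background.matrix(), A, combined.traces, n_passes=2)
        combined = ComponentSet(A, C).drop_empty()
    return combined, background


def _keep_main_blob(A: np.ndarray, fov_dims: tuple[int, int]) -> np.ndarray:
    """Footprint hygiene: zero every pixel not in the connected component
    holding the footprint's peak.  Disconnected satellite blobs are
    leftovers of neighboring sources, not part of this soma."""
    from skimage import measure

    A = A.copy()
    for i in range(A.shape[1]):
        img = A[:, i].reshape(fov_dims)
        if img.max() <= 0:
            continue
        labels = measure.label(img > 0, connectivity=2)
        keep = labels.ravel()[int(A[:, i].argmax())]
        A[labels.ravel() != keep, i] = 0.0
    return A


def run_batch(
    movie_source: str | Movie | MemmapMovie,
    params: BatchParams | None = None,
    out_path: str | None = None,
    classifier_model=None,
    workdir: str | None = None,
) -> tuple[ComponentSet, BackgroundModel, QualityReport]:
    """Full batch pipeline: memmap, patch CNMF, combine, quality filter,
    duplicate removal, final refinement, deconvolution.

    Movies may be given as a path (TIFF / HDF5 / .pmap), an in-memory
    :class:`Movie`, or an existing :class:`MemmapMovie`.  All components
    rejected is a legal outcome (returns an empty set with a warning).
    """
    import tempfile

    params = params or BatchParams()
    if isinstance(movie_source, MemmapMovie):
        mm = movie_source
    elif isinstance(movie_source, Movie):
        tmp = tempfile.NamedTemporaryFile(
            suffix=".pmap", delete=False, dir=workdir
        )
        tmp.close()
        mm = write_memmap(list(movie_source.frames()), tmp.name, frame_rate=movie_source.frame_rate)
    elif str(movie_source).endswith(".pmap"):
        mm = open_memmap(movie_source, frame_rate=params.frame_rate)
    else:
        mov = load_movie(movie_source, frame_rate=params.frame_rate)
        tmp = tempfile.NamedTemporaryFile(suffix=".pmap", delete=False, dir=workdir)
        tmp.close()
        mm = write_memmap(list(mov.frames()), tmp.name, frame_rate=mov.frame_rate)

    layout = construct_patches(mm.fov_dims, params.patch_size, params.overlap)
    comps, bg = process_in_patches(mm, layout, params, classifier_model=classifier_model)
    full = mm.to_movie()

    if comps.n_components > 0 and params.mode == "1p":
        radius = params.ring_radius or 2.0 * params.init.gaussian_width
        bg = ring_background(full, comps, ring_radius=radius)

    if comps.n_components > 0:
        report = evaluate_components(full, comps, bg, params.quality, classifier_model=classifier_model)
        comps = comps.select(report.accepted_indices).drop_empty()
    if comps.n_components == 0:
        logger.warning("run_batch: no components accepted")
        report = evaluate_components(full, comps, bg, params.quality)
        return comps, bg, report

    if comps.n_components > 1:
        scores = evaluate_components(full, comps, bg, params.quality, classifier_model=classifier_model)
        kept = detect_duplicates(comps, scores.snr, overlap_dup=params.quality.overlap_dup)
        comps = comps.select(kept)

    if params.final_hals_iterations > 0 and bg.kind == "low_rank":
        comps, bg = hals_refine(full, comps, bg, iterations=params.final_hals_iterations)

    if params.deconvolve and comps.n_components > 0:
        S = np.zeros_like(comps.traces)
        denoised = np.zeros_like(comps.traces)
        for i in range(comps.n_components):
            denoised[i], S[i] = oasis_deconvolve(comps.traces[i], DeconvParams())
        comps = ComponentSet(comps.footprints, comps.traces, deconvolved=S)

    report = evaluate_components(full, comps, bg, params.quality, classifier_model=classifier_model)
    if out_path is not None:
        save_result(out_path, comps, bg, report, params)
    return comps, bg, report


def save_result(
    path: str,
    components: ComponentSet,
    background: BackgroundModel,
    report: QualityReport,
    params: BatchParams,
) -> None:
    """Persist a pipeline result as HDF5: sparse A (CSC triplets), C, S,
    b, f, the quality report and full provenance attrs."""
    from caldemix import __version__

    A_sp = sparse.csc_matrix(components.footprints)
    with h5py.File(path, "w") as fh:
        g = fh.create_group("A")
        g.create_dataset("data", data=A_sp.data)
        g.create_dataset("indices", data=A_sp.indices)
        g.create_dataset("indptr", data=A_sp.indptr)
        g.create_dataset("shape", data=np.array(A_sp.shape))
        fh.create_dataset("C", data=components.traces)
        if components.deconvolved is not None:
            fh.create_dataset("S", data=components.deconvolved)
        if background.kind == "low_rank":
            fh.create_dataset("b", data=background.spatial)
            fh.create_dataset("f", data=background.temporal)
        q = fh.create_group("quality")
        q.create_dataset("space_correlation", data=report.space_correlation)
        q.create_dataset("snr", data=report.snr)
        q.create_dataset("classifier_score", data=report.classifier_score)
        q.create_dataset("accepted", data=report.accepted.astype(np.int8))
        fh.attrs["params"] = yaml.safe_dump(_params_dict(params))
        fh.attrs["seed"] = params.seed
        fh.attrs["version"] = __version__


def _params_dict(params: BatchParams) -> dict:
    from dataclasses import asdict

    out = asdict(params)
    out["patch_size"] = list(out["patch_size"])
    out["quality"]["peak_window"] = list(out["quality"]["peak_window"])
    return out


def load_result(path: str) -> tuple[ComponentSet, BackgroundModel, QualityReport]:
    with h5py.File(path, "r") as fh:
        g = fh["A"]
        A = sparse.csc_matrix(
            (g["data"][:], g["indices"][:], g["indptr"][:]), shape=tuple(g["shape"][:])
        ).toarray()
        C = fh["C"][:]
        S = fh["S"][:] if "S" in fh else None
        b = fh["b"][:] if "b" in fh else np.zeros((A.shape[0], 0))
        f = fh["f"][:] if "f" in fh else np.zeros((0, C.shape[1]))
        report = QualityReport(
            space_correlation=fh["quality/space_correlation"][:],
            snr=fh["quality/snr"][:],
            classifier_score=fh["quality/classifier_score"][:],
            accepted=fh["quality/accepted"][:].astype(bool),
        )
    comps = ComponentSet(A, C, deconvolved=S)
    bg = BackgroundModel(kind="low_rank", spatial=b, temporal=f)
    return comps, bg, report
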