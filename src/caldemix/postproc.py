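"""Post-processing: dF/F extraction and detection-performance metrics.

dF/F converts a component's arbitrary-unit fluorescence into relative
change over its baseline: the raw trace f_i = ||a_i||^2 (c_i + r_i) is
baseline-subtracted and divided by the baseline of f_i plus the background
fluorescence seen through the footprint, f0_i = BASELINE(f_i + B' a_i).
The baseline is the project-wide running percentile.

Detection metrics compare an extracted component set against reference
footprints by registration matching (precision / recall / F1), optionally
stratified by trace SNR with the conservative AND and permissive OR
variants that bracket the plain curves at every threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from caldemix._baseline import percentile_baseline
from caldemix.model import BackgroundModel, ComponentSet
from caldemix.registration import RegParams, register_pair

__all__ = ["DffParams", "EvalResult", "extract_dff", "match_components", "snr_stratified_metrics"]


@dataclass
class DffParams:
    """dF/F settings: running-percentile window (seconds), optional fixed
    percentile level in (0, 50] (None = automatic via the density mode),
    and whether the residual trace r_i enters f_i."""

    window_seconds: float = 100.0
    percentile: float | None = None
    use_residual: bool = True

    def __post_init__(self) -> None:
        if self.percentile is not None and not (0 < self.percentile <= 50):
            raise ValueError("percentile must lie in (0, 50]")


@dataclass
class EvalResult:
    precision: float
    recall: float
    f1: float
    matched_pairs: list[tuple[int, int]] = field(default_factory=list)
    thresholds: np.ndarray | None = None
    curves: dict = field(default_factory=dict)
    snr_gt: np.ndarray | None = None
    snr_cm: np.ndarray | None = None


def extract_dff(
    components: ComponentSet,
    background: BackgroundModel | None = None,
    residuals: np.ndarray | None = None,
    params: DffParams | None = None,
    frame_rate: float = 30.0,
    background_matrix: np.ndarray | None = None,
) -> np.ndarray:
    """dF/F traces (N x T) of all components.

    f_i = ||a_i||^2 (c_i + r_i)  (r_i omitted per ``use_residual``),
    f0_i = BASELINE(f_i + B' a_i),  dF/F_i = (f_i - BASELINE(f_i)) / f0_i.

    Raises when any f0 is non-positive (degenerate background), naming
    the component.
    """
    params = params or DffParams()
    A, C = components.footprints, components.traces
    N, T = C.shape
    if residuals is not None and params.use_residual:
        R = np.asarray(residuals, dtype=float)
    else:
        R = np.zeros_like(C)
    if background_matrix is not None:
        B = background_matrix
    elif background is not None and background.kind == "low_rank":
        B = background.spatial @ background.temporal
    else:
        B = None

    out = np.empty((N, T))
    for i in range(N):
        norm2 = float(A[:, i] @ A[:, i])
        f_i = norm2 * (C[i] + R[i])
        bg_proj = (B.T @ A[:, i]) if B is not None else np.zeros(T)
        f0 = percentile_baseline(f_i + bg_proj, frame_rate, params.window_seconds, params.percentile)
        if np.any(f0 <= 0):
            raise ValueError(f"component {i}: non-positive baseline fluorescence f0")
        base = percentile_baseline(f_i, frame_rate, params.window_seconds, params.percentile)
        out[i] = (f_i - base) / f0
    return out


def match_components(
    estimated: ComponentSet | np.ndarray,
    truth: np.ndarray,
    match_threshold: float = 0.7,
    binarize_threshold: float = 0.2,
) -> EvalResult:
    """Precision / recall / F1 of an extracted component set against
    reference footprints, matched by registration at the given Jaccard
    distance threshold.  Empty truth leaves recall (and F1) undefined
    (NaN) while precision is still computed."""
    A_est = estimated.footprints if isinstance(estimated, ComponentSet) else estimated
    params = RegParams(binarize_threshold=binarize_threshold, match_threshold=match_threshold)
    n_est, n_truth = A_est.shape[1], truth.shape[1]
    res = register_pair(A_est, truth, params=params)
    n_match = res.n_matched
    precision = n_match / n_est if n_est else np.nan
    recall = n_match / n_truth if n_truth else np.nan
    if np.isnan(recall) or np.isnan(precision) or (precision + recall) == 0:
        f1 = np.nan if (np.isnan(recall) or np.isnan(precision)) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return EvalResult(precision=precision, recall=recall, f1=f1, matched_pairs=res.matched_pairs)


def _ratio(num: int, den: int) -> float:
    return num / den if den else np.nan


def snr_stratified_metrics(
    snr_gt: np.ndarray,
    snr_cm: np.ndarray,
    thresholds: np.ndarray,
) -> EvalResult:
    """Precision / recall / F1 as a function of an SNR threshold.

    ``snr_gt`` and ``snr_cm`` are aligned per-pair SNRs of reference and
    extracted traces; false positives carry SNR 0 on the reference side
    and false negatives SNR 0 on the extracted side.  For each threshold
    three variants are computed: the plain curves, the conservative AND
    variant requiring both sides above threshold, and the permissive OR
    variant counting a pair above threshold when either side is (computed
    among present components).  The chain AND <= plain <= OR holds at
    every threshold (checked) with equality at threshold 0.
    """
    snr_gt = np.asarray(snr_gt, dtype=float)
    snr_cm = np.asarray(snr_cm, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("empty threshold grid")
    if snr_gt.shape != snr_cm.shape:
        raise ValueError("snr_gt and snr_cm must be aligned")

    matched = (snr_gt > 0) & (snr_cm > 0)
    best = np.maximum(snr_gt, snr_cm)
    curves: dict[str, dict[str, np.ndarray]] = {
        m: {v: np.empty(thresholds.size) for v in ("plain", "and", "or")}
        for m in ("precision", "recall", "f1")
    }

    def f1_of(p: float, r: float) -> float:
        if np.isnan(p) or np.isnan(r) or (p + r) == 0:
            return np.nan if (np.isnan(p) or np.isnan(r)) else 0.0
        return 2 * p * r / (p + r)

    for k, th in enumerate(thresholds):
        det = snr_cm > th
        ref = snr_gt > th
        prec = _ratio(int((det & (snr_gt > 0)).sum()), int(det.sum()))
        rec = _ratio(int((ref & (snr_cm > 0)).sum()), int(ref.sum()))
        prec_and = _ratio(int((det & ref).sum()), int(det.sum()))
        rec_and = _ratio(int((ref & det).sum()), int(ref.sum()))
        above_or = best > th
        prec_or = _ratio(int((above_or & matched).sum()), int((above_or & (snr_cm > 0)).sum()))
        rec_or = _ratio(int((above_or & matched).sum()), int((above_or & (snr_gt > 0)).sum()))
        for name, vals in (
            ("precision", (prec, prec_and, prec_or)),
            ("recall", (rec, rec_and, rec_or)),
        ):
            curves[name]["plain"][k], curves[name]["and"][k], curves[name]["or"][k] = vals
        curves["f1"]["plain"][k] = f1_of(prec, rec)
        curves["f1"]["and"][k] = f1_of(prec_and, rec_and)
        curves["f1"]["or"][k] = f1_of(prec_or, rec_or)

    for m in curves:
        lo, mid, hi = curves[m]["and"], curves[m]["plain"], curves[m]["or"]
        ok = np.isfinite(lo) & np.isfinite(mid) & np.isfinite(hi)
        if np.any(lo[ok] > mid[ok] + 1e-12) or np.any(mid[ok] > hi[ok] + 1e-12):
            raise AssertionError(f"bound ordering AND <= plain <= OR violated for {m}")

    n_match = int(matched.sum())
    precision = _ratio(n_match, int((snr_cm > 0).sum()))
    recall = _ratio(n_match, int((snr_gt > 0).sum()))
    return EvalResult(
        precision=precision,
        recall=recall,
        f1=f1_of(precision, recall),
        thresholds=thresholds,
        curves=curves,
        snr_gt=snr_gt,
        snr_cm=snr_cm,
    )
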