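"""Nonnegative factorization primitives shared by initialization, batch
refinement and the streaming pipeline.

All updates are exact blockwise coordinate minimizations (hierarchical
alternating least squares), so each call can only decrease the Frobenius
objective it addresses — the property the batch refinement loop asserts.
"""

from __future__ import annotations

import numpy as np
from sklearn.decomposition import NMF

__all__ = ["rank1_nmf", "hals_traces", "hals_footprints", "nonneg_ls_columns", "nnmf"]


def rank1_nmf(
    X: np.ndarray,
    n_iter: int = 10,
    tol: float = 1e-4,
    init_c: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Best nonnegative rank-1 approximation X ~ a c' by alternating exact
    updates.  ``init_c`` seeds the temporal factor (default: the row of X
    with the largest variance, rectified)."""
    X = np.asarray(X, dtype=float)
    if init_c is None:
        row = int(np.argmax(X.var(axis=1)))
        c = np.maximum(X[row], 0.0)
    else:
        c = np.maximum(np.asarray(init_c, dtype=float).copy(), 0.0)
    if c.max() <= 0:
        c = np.maximum(X.mean(axis=0), 0.0)
    if c.max() <= 0:
        return np.zeros(X.shape[0]), np.zeros(X.shape[1])
    a = np.zeros(X.shape[0])
    prev_obj = np.inf
    for _ in range(max(n_iter, 1)):
        cc = float(c @ c)
        if cc == 0:
            break
        a = np.maximum(X @ c, 0.0) / cc
        aa = float(a @ a)
        if aa == 0:
            break
        c = np.maximum(X.T @ a, 0.0) / aa
        obj = float(np.linalg.norm(X - np.outer(a, c)))
        if prev_obj - obj < tol * max(prev_obj, 1e-12):
            break
        prev_obj = obj
    return a, c


def hals_traces(
    Y: np.ndarray, A: np.ndarray, C: np.ndarray, n_passes: int = 2
) -> np.ndarray:
    """Coordinate descent on argmin_{C >= 0} ||Y - A C||_F, warm-started at
    C.  Rows whose footprint is never active (zero Gram diagonal) are left
    untouched."""
    C = np.asarray(C, dtype=float).copy()
    if A.shape[1] == 0:
        return C
    AtA = A.T @ A
    AtY = A.T @ Y
    diag = np.diag(AtA)
    for _ in range(n_passes):
        for i in range(A.shape[1]):
            if diag[i] == 0:
                continue
            C[i] = np.maximum(C[i] + (AtY[i] - AtA[i] @ C) / diag[i], 0.0)
    return C


def hals_footprints(
    Y: np.ndarray,
    A: np.ndarray,
    C: np.ndarray,
    support: np.ndarray | None = None,
    n_passes: int = 2,
) -> np.ndarray:
    """Coordinate descent on argmin_{A >= 0} ||Y - A C||_F with optional
    per-column boolean support masks (d x N): entries outside the mask stay
    zero."""
    A = np.asarray(A, dtype=float).copy()
    if A.shape[1] == 0:
        return A
    CCt = C @ C.T
    YCt = Y @ C.T
    diag = np.diag(CCt)
    for _ in range(n_passes):
        for i in range(A.shape[1]):
            if diag[i] == 0:
                continue
            col = np.maximum(A[:, i] + (YCt[:, i] - A @ CCt[:, i]) / diag[i], 0.0)
            if support is not None:
                col[~support[:, i]] = 0.0
            A[:, i] = col
    return A


def nonneg_ls_columns(
    Y: np.ndarray, F: np.ndarray, X: np.ndarray | None = None, n_passes: int = 5
) -> np.ndarray:
    """argmin_{X >= 0} ||Y - X F||_F by HALS over the columns of X
    (shape d x k for F of shape k x T)."""
    k = F.shape[0]
    if X is None:
        X = np.zeros((Y.shape[0], k))
    return hals_footprints(Y, X, F, n_passes=n_passes)


def nnmf(X: np.ndarray, rank: int, seed: int = 0, max_iter: int = 300) -> tuple[np.ndarray, np.ndarray]:
    """Rank-``rank`` nonnegative factorization X ~ W H (negative entries of
    X are clipped first), polished with a few exact HALS passes."""
    if rank == 0:
        return np.zeros((X.shape[0], 0)), np.zeros((0, X.shape[1]))
    Xp = np.maximum(np.asarray(X, dtype=float), 0.0)
    if Xp.max() == 0:
        return np.zeros((X.shape[0], rank)), np.zeros((rank, X.shape[1]))
    rank = min(rank, min(Xp.shape))
    model = NMF(
        n_components=rank, init="nndsvda", random_state=seed, max_iter=max_iter, tol=1e-6
    )
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        # the HALS polish below finishes the job; the iteration cap is fine
        warnings.simplefilter("ignore", ConvergenceWarning)
        W = model.fit_transform(Xp)
    H = model.components_
    for _ in range(5):
        H = hals_traces(Xp, W, H, n_passes=1)
        W = hals_footprints(Xp, W, H, n_passes=1)
    return W, H
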