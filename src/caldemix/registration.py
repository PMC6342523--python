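"""Component registration across imaging sessions.

Footprints from two sessions are binarized (threshold at a fraction of
each footprint's maximum), compared with the Jaccard distance
1 - |intersection| / |union|, and matched by solving the linear assignment
problem (Hungarian method) over the resulting distance matrix.  Distances
above a threshold are set to infinity and can never be matched, which both
prevents false pairings between marginally overlapping cells and lets
sessions have different neuron counts.  A mask strictly contained in the
other is distance 0 regardless of the Jaccard value (manual annotations
tend to be conservative subsets of extracted footprints).

Multi-session registration proceeds chronologically, maintaining the
union of all distinct components seen so far and registering each new
session against that union, so non-consecutive sessions can be compared
through the union without direct pairwise registration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.signal import fftconvolve

__all__ = [
    "RegParams",
    "RegistrationResult",
    "binarize_footprint",
    "pair_distance",
    "register_pair",
    "register_multi",
    "transitivity_index",
]

_INF_COST = 1e9  # stand-in for infinity inside the assignment solver


@dataclass
class RegParams:
    """Registration thresholds: ``binarize_threshold`` (fraction of each
    footprint's max kept in its binary mask) and ``match_threshold`` (the
    Jaccard distance above which components are declared non-matching)."""

    binarize_threshold: float = 0.2
    match_threshold: float = 0.5
    alignment: str = "none"  # "none" or "rigid"

    def __post_init__(self) -> None:
        if not (0 < self.binarize_threshold < 1):
            raise ValueError("binarize_threshold must lie in (0, 1)")
        if not (0 < self.match_threshold <= 1):
            raise ValueError("match_threshold must lie in (0, 1]")
        if self.alignment not in {"none", "rigid"}:
            raise ValueError("alignment must be 'none' or 'rigid'")


@dataclass
class RegistrationResult:
    matched_pairs: list[tuple[int, int]]
    unmatched_1: list[int]
    unmatched_2: list[int]
    distance_matrix: np.ndarray
    union_footprints: np.ndarray | None = None
    matchings: list[np.ndarray] = field(default_factory=list)

    @property
    def n_matched(self) -> int:
        return len(self.matched_pairs)

    @property
    def total_distance(self) -> float:
        return float(
            sum(self.distance_matrix[i, j] for i, j in self.matched_pairs)
        )


def binarize_footprint(a: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """Binary mask of a footprint: 1 where a >= threshold * max(a)."""
    a = np.asarray(a, dtype=float)
    peak = a.max()
    if peak <= 0:
        raise ValueError("cannot binarize an all-zero footprint")
    return a >= threshold * peak


def pair_distance(
    a1: np.ndarray,
    a2: np.ndarray,
    binarize_threshold: float = 0.2,
    match_threshold: float = 0.5,
) -> float:
    """Registration distance between two footprints on one pixel grid.

    1 - Jaccard(m1, m2) when at or below ``match_threshold``; 0 when one
    mask contains the other (even if the Jaccard distance is larger);
    infinity otherwise.
    """
    m1 = binarize_footprint(a1, binarize_threshold)
    m2 = binarize_footprint(a2, binarize_threshold)
    inter = int(np.count_nonzero(m1 & m2))
    union = int(np.count_nonzero(m1 | m2))
    if inter == m1.sum() or inter == m2.sum():  # containment (either way)
        return 0.0
    dist = 1.0 - inter / union
    return dist if dist <= match_threshold else np.inf


def _rigid_shift(templates: tuple[np.ndarray, np.ndarray]) -> tuple[int, int]:
    """Integer-pixel translation aligning template 1 onto template 2 via
    the cross-correlation peak."""
    t1, t2 = templates
    x1 = t1 - t1.mean()
    x2 = t2 - t2.mean()
    xc = fftconvolve(x2, x1[::-1, ::-1], mode="full")
    peak = np.unravel_index(np.argmax(xc), xc.shape)
    return peak[0] - (t1.shape[0] - 1), peak[1] - (t1.shape[1] - 1)


def _apply_shift(A: np.ndarray, fov: tuple[int, int], shift: tuple[int, int]) -> np.ndarray:
    rows, cols = fov
    dy, dx = shift
    out = np.zeros_like(A)
    for i in range(A.shape[1]):
        img = A[:, i].reshape(rows, cols)
        shifted = np.zeros_like(img)
        src_r = slice(max(0, -dy), rows - max(0, dy))
        src_c = slice(max(0, -dx), cols - max(0, dx))
        dst_r = slice(max(0, dy), rows - max(0, -dy))
        dst_c = slice(max(0, dx), cols - max(0, -dx))
        shifted[dst_r, dst_c] = img[src_r, src_c]
        out[:, i] = shifted.ravel()
    return out


def register_pair(
    A1: np.ndarray,
    A2: np.ndarray,
    template1: np.ndarray | None = None,
    template2: np.ndarray | None = None,
    params: RegParams | None = None,
) -> RegistrationResult:
    """Optimally match the components of two sessions.

    With rigid alignment on, session 1's footprints are first translated
    onto session 2's template by the integer-pixel cross-correlation peak
    of the two templates (out-of-FOV pixels dropped).  The Hungarian
    method then minimizes the total finite distance; infinite pairs are
    never matched.  An empty session simply leaves the other side fully
    unmatched.
    """
    params = params or RegParams()
    N1, N2 = A1.shape[1], A2.shape[1]
    A1_use = A1
    if params.alignment == "rigid":
        if template1 is None or template2 is None:
            raise ValueError("rigid alignment requires both templates")
        shift = _rigid_shift((template1, template2))
        A1_use = _apply_shift(A1, template1.shape, shift)

    D = np.full((N1, N2), np.inf)
    for i in range(N1):
        if A1_use[:, i].max() <= 0:
            continue
        for j in range(N2):
            D[i, j] = pair_distance(
                A1_use[:, i], A2[:, j], params.binarize_threshold, params.match_threshold
            )

    matched: list[tuple[int, int]] = []
    if N1 > 0 and N2 > 0:
        cost = np.where(np.isfinite(D), D, _INF_COST)
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if np.isfinite(D[i, j]):
                matched.append((int(i), int(j)))
    matched_1 = {i for i, _ in matched}
    matched_2 = {j for _, j in matched}
    return RegistrationResult(
        matched_pairs=matched,
        unmatched_1=[i for i in range(N1) if i not in matched_1],
        unmatched_2=[j for j in range(N2) if j not in matched_2],
        distance_matrix=D,
        union_footprints=A1_use,
    )


def register_multi(
    sessions: list[tuple[np.ndarray, np.ndarray | None]],
    params: RegParams | None = None,
) -> RegistrationResult:
    """Register chronologically ordered sessions against a running union.

    The union starts as session 1; each subsequent session is registered
    against it, matched union members are replaced by the newer footprints
    and unmatched new components appended.  ``matchings[s][j]`` is the
    union index of component j of session s.
    """
    params = params or RegParams()
    if len(sessions) < 2:
        raise ValueError("multi-session registration needs at least 2 sessions")
    A_u = sessions[0][0].copy()
    template_u = sessions[0][1]
    matchings: list[np.ndarray] = [np.arange(A_u.shape[1])]
    k_tot = A_u.shape[1]
    all_pairs: list[tuple[int, int]] = []
    for A_i, template_i in sessions[1:]:
        res = register_pair(A_u, A_i, template_u, template_i, params)
        m = np.full(A_i.shape[1], -1, dtype=int)
        for u_idx, i_idx in res.matched_pairs:
            A_u[:, u_idx] = A_i[:, i_idx]  # keep the newer footprint
            m[i_idx] = u_idx
        if res.unmatched_2:
            A_u = np.concatenate([A_u, A_i[:, res.unmatched_2]], axis=1)
            m[res.unmatched_2] = np.arange(k_tot, k_tot + len(res.unmatched_2))
            k_tot += len(res.unmatched_2)
        matchings.append(m)
        template_u = template_i
        all_pairs.extend(res.matched_pairs)
    return RegistrationResult(
        matched_pairs=all_pairs,
        unmatched_1=[],
        unmatched_2=[],
        distance_matrix=np.zeros((0, 0)),
        union_footprints=A_u,
        matchings=matchings,
    )


def transitivity_index(
    A1: np.ndarray,
    A2: np.ndarray,
    A3: np.ndarray,
    templates: tuple | None = None,
    params: RegParams | None = None,
) -> float | None:
    """Consistency of chained pairwise matchings across three sessions.

    Over components matched both 1->2 and 2->3, the fraction whose direct
    1->3 match equals the composition of the two.  None when no chains
    are composable.
    """
    params = params or RegParams()
    t1 = t2 = t3 = None
    if templates is not None:
        t1, t2, t3 = templates
    m12 = {i: j for i, j in register_pair(A1, A2, t1, t2, params).matched_pairs}
    m23 = {i: j for i, j in register_pair(A2, A3, t2, t3, params).matched_pairs}
    m13 = {i: j for i, j in register_pair(A1, A3, t1, t3, params).matched_pairs}
    chains = [(i, m23[m12[i]]) for i in m12 if m12[i] in m23]
    if not chains:
        return None
    agree = sum(1 for i, k in chains if m13.get(i) == k)
    return agree / len(chains)
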