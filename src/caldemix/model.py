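"""Core containers shared across the pipeline: component sets and
background models for the decomposition Y = A C + B + E."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = ["ComponentSet", "BackgroundModel"]


@dataclass
class ComponentSet:
    """Paired spatial footprints A (d x N) and temporal traces C (N x T),
    plus optional deconvolved activity S (N x T)."""

    footprints: np.ndarray
    traces: np.ndarray
    deconvolved: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.footprints.ndim != 2 or self.traces.ndim != 2:
            raise ValueError("footprints and traces must be 2-D")
        if self.footprints.shape[1] != self.traces.shape[0]:
            raise ValueError(
                f"A has {self.footprints.shape[1]} columns but C has {self.traces.shape[0]} rows"
            )

    @property
    def n_components(self) -> int:
        return self.footprints.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.footprints.shape[0]

    def reconstruct(self) -> np.ndarray:
        return self.footprints @ self.traces

    def select(self, indices) -> "ComponentSet":
        indices = np.asarray(indices, dtype=int)
        return ComponentSet(
            footprints=self.footprints[:, indices],
            traces=self.traces[indices],
            deconvolved=None if self.deconvolved is None else self.deconvolved[indices],
        )

    def drop_empty(self) -> "ComponentSet":
        """Remove all-zero footprints (no stage may retain them)."""
        keep = np.flatnonzero(np.abs(self.footprints).sum(axis=0) > 0)
        return self.select(keep)

    @staticmethod
    def empty(d: int, T: int) -> "ComponentSet":
        return ComponentSet(np.zeros((d, 0)), np.zeros((0, T)))

    @staticmethod
    def concatenate(sets: list["ComponentSet"]) -> "ComponentSet":
        sets = [s for s in sets if s.n_components > 0]
        if not sets:
            raise ValueError("nothing to concatenate")
        return ComponentSet(
            footprints=np.concatenate([s.footprints for s in sets], axis=1),
            traces=np.concatenate([s.traces for s in sets], axis=0),
        )


@dataclass
class BackgroundModel:
    """Background/neuropil model: low-rank B = b f (two-photon) or the
    ring-weight form B = W (Y - A C) (one-photon microendoscopic data)."""

    kind: str  # "low_rank" or "ring"
    spatial: np.ndarray | None = None  # b: (d, n_b)
    temporal: np.ndarray | None = None  # f: (n_b, T)
    ring_weights: sparse.spmatrix | None = None  # W: (d, d)
    ring_radius: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"low_rank", "ring"}:
            raise ValueError(f"unknown background kind {self.kind!r}")
        if self.kind == "low_rank":
            if self.spatial is None or self.temporal is None:
                raise ValueError("low_rank background requires spatial and temporal factors")
            if self.spatial.shape[1] != self.temporal.shape[0]:
                raise ValueError("b and f rank mismatch")
        if self.kind == "ring" and self.ring_weights is None:
            raise ValueError("ring background requires a weight matrix")

    @property
    def rank(self) -> int:
        return 0 if self.spatial is None else self.spatial.shape[1]

    def matrix(self, movie_data: np.ndarray | None = None, components: ComponentSet | None = None) -> np.ndarray:
        """Dense background matrix B (d x T)."""
        if self.kind == "low_rank":
            return self.spatial @ self.temporal
        if movie_data is None or components is None:
            raise ValueError("ring background needs the movie and components to form B")
        return np.asarray(self.ring_weights @ (movie_data - components.reconstruct()))

    @staticmethod
    def empty(d: int, T: int) -> "BackgroundModel":
        return BackgroundModel(kind="low_rank", spatial=np.zeros((d, 0)), temporal=np.zeros((0, T)))
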