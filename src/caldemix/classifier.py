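"""Learned footprint classifier trained on synthetic crops.

Complements the deterministic geometric scorer in :mod:`caldemix.quality`
with a supervised model: a small multilayer perceptron on downsampled
footprint crops, trained on synthetic positives (Gaussian and donut-shaped
somata) versus negatives (noise fields, edges, blob fragments and
elongated shapes).  Training data is generated on the fly from a seed, so
no weights ship with the package and retraining is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import transform
from sklearn.neural_network import MLPClassifier

__all__ = ["FootprintClassifier", "generate_crops", "train_footprint_classifier"]

_INPUT_SIDE = 24


@dataclass
class FootprintClassifier:
    """Wrapper exposing ``score_crops`` over a fitted sklearn estimator."""

    estimator: MLPClassifier
    input_side: int = _INPUT_SIDE

    def score_crops(self, crops: np.ndarray) -> np.ndarray:
        X = _featurize(np.asarray(crops, dtype=float), self.input_side)
        return self.estimator.predict_proba(X)[:, 1]


def _featurize(crops: np.ndarray, side: int) -> np.ndarray:
    if crops.ndim == 2:
        crops = crops[None]
    out = np.empty((crops.shape[0], side * side))
    for k, crop in enumerate(crops):
        peak = crop.max()
        norm = crop / peak if peak > 0 else crop
        if norm.shape != (side, side):
            norm = transform.resize(norm, (side, side), order=1, anti_aliasing=True)
        out[k] = norm.ravel()
    return out


def _soma(rng: np.random.Generator, side: int) -> np.ndarray:
    """Round or donut-shaped positive example with mild noise."""
    rr, cc = np.mgrid[0:side, 0:side]
    cy, cx = side / 2 + rng.uniform(-2, 2), side / 2 + rng.uniform(-2, 2)
    sigma = rng.uniform(side / 10, side / 5)
    d2 = (rr - cy) ** 2 + (cc - cx) ** 2
    img = np.exp(-d2 / (2 * sigma**2))
    if rng.random() < 0.4:  # donut: suppress the nucleus
        img *= 1.0 - rng.uniform(0.5, 0.9) * np.exp(-d2 / (2 * (sigma / 2) ** 2))
    img += rng.normal(0, 0.03, img.shape)
    return np.clip(img, 0, None)


def _non_soma(rng: np.random.Generator, side: int) -> np.ndarray:
    """Negative example: noise, edge, fragment, elongated process or an
    oversized diffuse blob (background leakage looks like a compact bump
    that fills the whole crop)."""
    kind = rng.integers(0, 5)
    rr, cc = np.mgrid[0:side, 0:side]
    if kind == 0:  # unstructured noise
        img = np.abs(rng.normal(0, 1, (side, side)))
    elif kind == 1:  # straight edge / gradient
        angle = rng.uniform(0, np.pi)
        proj = np.cos(angle) * rr + np.sin(angle) * cc
        img = (proj > np.median(proj)).astype(float) + rng.normal(0, 0.1, (side, side))
    elif kind == 2:  # partial soma cut by the crop border
        img = _soma(rng, side)
        half = rng.integers(0, 4)
        sl = [slice(None)] * 2
        sl[half // 2] = slice(0, side // 2) if half % 2 else slice(side // 2, None)
        img[tuple(sl)] = 0
        img = np.roll(img, rng.integers(side // 3, side // 2), axis=half // 2)
    elif kind == 3:  # elongated dendrite-like streak
        angle = rng.uniform(0, np.pi)
        d = np.abs(np.sin(angle) * (rr - side / 2) - np.cos(angle) * (cc - side / 2))
        img = np.exp(-(d**2) / (2 * rng.uniform(1, 2) ** 2))
        img += rng.normal(0, 0.05, (side, side))
    else:  # oversized diffuse blob filling the crop
        cy, cx = side / 2 + rng.uniform(-3, 3), side / 2 + rng.uniform(-3, 3)
        sigma = rng.uniform(side / 2.5, side)
        d2 = (rr - cy) ** 2 + (cc - cx) ** 2
        img = np.exp(-d2 / (2 * sigma**2)) + rng.normal(0, 0.03, (side, side))
    return np.clip(img, 0, None)


def generate_crops(
    n: int, seed: int = 0, side: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced synthetic crop set: returns (crops (n, side, side), labels)."""
    rng = np.random.default_rng(seed)
    crops = np.empty((n, side, side))
    labels = np.empty(n, dtype=int)
    for k in range(n):
        labels[k] = k % 2
        img = _soma(rng, side) if labels[k] else _non_soma(rng, side)
        peak = img.max()
        crops[k] = img / peak if peak > 0 else img
    return crops, labels


def train_footprint_classifier(
    n_train: int = 2000, seed: int = 0, input_side: int = _INPUT_SIDE
) -> FootprintClassifier:
    """Train the MLP footprint classifier on synthetic crops."""
    crops, labels = generate_crops(n_train, seed=seed)
    X = _featurize(crops, input_side)
    est = MLPClassifier(
        hidden_layer_sizes=(64, 32),
        max_iter=300,
        random_state=seed,
        early_stopping=True,
    )
    est.fit(X, labels)
    return FootprintClassifier(estimator=est, input_side=input_side)
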