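"""Global intensity-threshold baseline predictor.

A two-parameter monotone map: zero at or below a learned intensity
threshold, then a squashed, strictly increasing prediction in (0, 1).
Mathematically equivalent to a single-pixel ReLU-then-sigmoid network, so
it is fitted directly by minimizing per-pixel binary cross-entropy over
(threshold, gain).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import optimize

_CLIP = 1e-7


@dataclass
class ThresholdModel:
    threshold: float
    gain: float

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Pixelwise prediction; 0 at or below threshold, (0, 1) above."""
        x = np.asarray(image, dtype=np.float64)
        z = self.gain * np.maximum(0.0, x - self.threshold)
        # 2*sigmoid(z) - 1: equals 0 at z = 0, strictly increasing, < 1
        return 2.0 / (1.0 + np.exp(-z)) - 1.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"threshold": self.threshold, "gain": self.gain}, fh)

    @classmethod
    def from_json(cls, path) -> "ThresholdModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(threshold=float(d["threshold"]), gain=float(d["gain"]))


def bce_loss(pred: np.ndarray, target: np.ndarray) -> float:
    p = np.clip(pred, _CLIP, 1.0 - _CLIP)
    t = np.clip(target, 0.0, 1.0)
    return float(np.mean(-t * np.log(p) - (1.0 - t) * np.log(1.0 - p)))


def _loss(params: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    t, g = params
    model = ThresholdModel(threshold=float(t), gain=float(np.abs(g)))
    return bce_loss(model.predict(x), y)


def fit_threshold(
    images,
    gt,
    epochs: int = 50,
    max_pixels: int = 200_000,
    seed: int = 0,
    n_restarts: int = 5,
) -> ThresholdModel:
    """Fit (threshold, gain) by minimizing mean per-pixel BCE.

    ``images`` and ``gt`` are aligned sequences of 2-D arrays (or a single
    pair).  Pixels are pooled (and subsampled above ``max_pixels``); the
    optimizer runs Nelder-Mead from several seeded starts, mirroring the
    effect of epoch-based training without the dead-ReLU local optima.
    ``epochs`` scales the iteration budget for interface parity.
    """
    if isinstance(images, np.ndarray) and images.ndim == 2:
        images, gt = [images], [gt]
    x = np.concatenate([np.asarray(im, dtype=np.float64).ravel() for im in images])
    y = np.concatenate([np.asarray(g, dtype=np.float64).ravel() for g in gt])
    if x.shape != y.shape:
        raise ValueError("images and ground truth are not aligned")
    ybin = y > 0
    if ybin.all() or not ybin.any():
        raise ValueError("degenerate ground truth: need specular and "
                         "non-specular pixels")
    rng = np.random.default_rng(seed)
    if x.size > max_pixels:
        idx = rng.choice(x.size, size=max_pixels, replace=False)
        x, y = x[idx], y[idx]

    maxiter = max(50, 4 * epochs)
    best = None
    for _ in range(n_restarts):
        t0 = rng.uniform(0.3, 0.95)
        g0 = rng.uniform(5.0, 80.0)
        res = optimize.minimize(
            _loss, np.array([t0, g0]), args=(x, y), method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-5, "fatol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    t, g = best.x
    return ThresholdModel(threshold=float(np.clip(t, 0.0, 1.0)),
                          gain=float(np.abs(g)))


def grid_search_threshold(x: np.ndarray, y: np.ndarray,
                          n_t: int = 200, n_g: int = 40) -> tuple[ThresholdModel, float]:
    """Exhaustive (threshold, gain) grid search oracle over the same loss."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    best_loss, best = np.inf, None
    for t in np.linspace(0.0, 1.0, n_t):
        for g in np.geomspace(1.0, 500.0, n_g):
            loss = _loss(np.array([t, g]), x, y)
            if loss < best_loss:
                best_loss, best = loss, (t, g)
    return ThresholdModel(threshold=float(best[0]), gain=float(best[1])), best_loss
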