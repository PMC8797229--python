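"""Pixelwise-weighted binary cross-entropy.

The per-pixel binary cross-entropy is multiplied elementwise with a weight
map and the total is normalised by the sum of that sample's weight map, so
every training sample updates the model by a comparable amount regardless of
how much weight its map carries.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-7

__all__ = ["EPS", "bce_map", "weighted_bce", "weighted_bce_grad"]


def bce_map(gt: np.ndarray, pred: np.ndarray, eps: float = EPS) -> np.ndarray:
    """Per-pixel binary cross-entropy with predictions clipped to
    [eps, 1 - eps]."""
    gt = np.asarray(gt, dtype=np.float64)
    p = np.clip(np.asarray(pred, dtype=np.float64), eps, 1.0 - eps)
    return -(gt * np.log(p) + (1.0 - gt) * np.log1p(-p))


def weighted_bce(gt: np.ndarray, pred: np.ndarray, weights: np.ndarray,
                 eps: float = EPS) -> float:
    """sum(w * bce) / sum(w) over all pixels of one sample."""
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    w = np.asarray(weights, dtype=np.float64)
    if not (gt.shape == pred.shape == w.shape):
        raise ValueError(
            f"shape mismatch: gt {gt.shape}, pred {pred.shape}, w {w.shape}")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("sum of weights must be positive")
    return float((w * bce_map(gt, pred, eps)).sum() / total)


def weighted_bce_grad(gt: np.ndarray, pred: np.ndarray, weights: np.ndarray,
                      eps: float = EPS) -> np.ndarray:
    """d(weighted_bce)/d(pred), elementwise; zero where pred is clipped."""
    gt = np.asarray(gt, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    total = w.sum()
    if total <= 0:
        raise ValueError("sum of weights must be positive")
    p = np.clip(pred, eps, 1.0 - eps)
    g = w * (p - gt) / (p * (1.0 - p)) / total
    g[(pred < eps) | (pred > 1.0 - eps)] = 0.0
    return g
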