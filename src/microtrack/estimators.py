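"""Scikit-learn style estimators wrapping the two trainable models.

``UNetSegmenter`` learns phase-contrast frame -> cell-probability plane;
``UNetTracker`` learns stacked 4-plane tracking sample -> target-cell
probability plane.  Both follow the sklearn estimator contract
(``get_params``/``set_params``, ``fit`` returning self, fitted attributes
with trailing underscores) so they compose with sklearn model selection.

Default hyperparameters are the full-scale training profile (depth 4, 64
base filters; segmentation 600 epochs x 300 steps, batch 1, Adam 1e-4;
tracking 500 epochs x 300 steps, batch 2, Adam 1e-5).  The test-suite and
the bundled pipelines use the desk-scale profile (depth 3, 16 filters,
far fewer steps), which trains in minutes on one CPU core.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
from sklearn.base import BaseEstimator

from . import augment as aug
from .io import normalize_frame
from .seg import segment_frame
from .unet import UNetSpec, build_model, train
from .weights import WeightParams, make_seg_target

__all__ = ["UNetSegmenter", "UNetTracker"]


class _UNetBase(BaseEstimator):
    def _spec(self, in_planes: int) -> UNetSpec:
        return UNetSpec(in_planes=in_planes, depth=self.depth,
                        base_filters=self.base_filters, seed=self.seed)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted yet; call fit first")


class UNetSegmenter(_UNetBase):
    """U-Net cell segmentation of phase-contrast frames.

    fit(X, y): X is (n, H, W) raw phase intensities, y is (n, H, W) integer
    label masks (0 = background).  Training samples are random crops with
    flip/rotation, illumination, blur and noise augmentation; targets and
    weight maps are derived from the label masks (border-eroded binary GT,
    skeleton/border-emphasising weights, variable background weighting).
    """

    def __init__(self, depth: int = 4, base_filters: int = 64,
                 epochs: int = 600, steps_per_epoch: int = 300,
                 batch_size: int = 1, learning_rate: float = 1e-4,
                 crop_size: int = 64, threshold: float = 0.5,
                 min_area: int = 20, sigma_blur: float = 1.0,
                 sigma_noise: float = 0.03,
                 variable_background: bool = True, seed: int = 0):
        self.depth = depth
        self.base_filters = base_filters
        self.epochs = epochs
        self.steps_per_epoch = steps_per_epoch
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.crop_size = crop_size
        self.threshold = threshold
        self.min_area = min_area
        self.sigma_blur = sigma_blur
        self.sigma_noise = sigma_noise
        self.variable_background = variable_background
        self.seed = seed

    def _sample_stream(self, X, y, targets, rng) -> Iterator:
        n, H, W = X.shape
        c = min(self.crop_size, H, W)
        # frames weighted by cell count and crops centred near cells, so
        # crowded neighbourhoods (the hard part) dominate the stream
        counts = np.array([len(np.unique(f)) - 1 for f in y], dtype=float)
        frame_p = (counts + 1.0) / (counts + 1.0).sum()
        centroids = []
        for f in y:
            ids = np.unique(f)
            ids = ids[ids > 0]
            pts = (np.array([np.argwhere(f == l).mean(axis=0) for l in ids])
                   if len(ids) else np.empty((0, 2)))
            centroids.append(pts)
        while True:
            i = int(rng.choice(n, p=frame_p))
            pts = centroids[i]
            if len(pts) and rng.random() < 0.8:
                cy, cx = pts[int(rng.integers(len(pts)))]
                r = int(np.clip(cy - c // 2 + rng.integers(-16, 17),
                                0, H - c))
                col = int(np.clip(cx - c // 2 + rng.integers(-16, 17),
                                  0, W - c))
            else:
                r = int(rng.integers(H - c + 1))
                col = int(rng.integers(W - c + 1))
            img = X[i, r:r + c, col:col + c]
            tgt = targets[i]
            gt = tgt.gt[r:r + c, col:col + c].astype(np.float64)
            wm = tgt.weights[r:r + c, col:col + c]
            k = int(rng.integers(4))
            if k:
                img, gt, wm = (np.rot90(a, k) for a in (img, gt, wm))
            if rng.random() < 0.5:
                img, gt, wm = (a[::-1] for a in (img, gt, wm))
            img = aug.random_illumination(
                img, aug.AugmentConfig(sigma_blur=self.sigma_blur,
                                       sigma_noise=self.sigma_noise), rng)
            img = aug.gaussian_blur(img, self.sigma_blur * rng.random())
            img = aug.add_noise(img, self.sigma_noise * rng.random(), rng)
            yield img[None].copy(), gt.copy(), np.ascontiguousarray(wm)

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 3 or y.shape != X.shape:
            raise ValueError("X and y must both be (n_frames, H, W)")
        X = np.stack([normalize_frame(f) for f in X])
        params = WeightParams()
        targets = [make_seg_target(frame, params) for frame in y]
        rng = np.random.default_rng(self.seed)
        self.model_ = build_model(self._spec(in_planes=1))
        result = train(
            self.model_, self._sample_stream(X, y, targets, rng),
            epochs=self.epochs, steps_per_epoch=self.steps_per_epoch,
            batch_size=self.batch_size, learning_rate=self.learning_rate,
            variable_background=self.variable_background,
        )
        self.loss_history_ = result.loss_history
        self.epoch_losses_ = result.epoch_losses
        self.n_iter_ = len(result.loss_history)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Cell-probability planes for (n, H, W) raw frames."""
        self._check_fitted()
        X = np.asarray(X, dtype=np.float64)
        return np.stack([self.model_.predict(normalize_frame(f)) for f in X])

    def predict(self, X) -> list[np.ndarray]:
        """Integer label masks for (n, H, W) raw frames."""
        self._check_fitted()
        X = np.asarray(X, dtype=np.float64)
        return [segment_frame(normalize_frame(f), self.model_,
                              threshold=self.threshold,
                              min_area=self.min_area) for f in X]


class UNetTracker(_UNetBase):
    """U-Net frame-to-frame tracking head.

    fit(X, y, sample_weight): X is (n, 4, h, w) stacked tracking samples
    (previous phase, query-cell mask, current phase, all-current-cells
    mask), y the (n, h, w) binary target (tracked cell, or both daughters),
    sample_weight the per-pixel weight maps (defaults to uniform).  The
    inter-frame shift augmentation translates the current-frame planes (and
    target/weights) by a common random vector each step.
    """

    def __init__(self, depth: int = 4, base_filters: int = 64,
                 epochs: int = 500, steps_per_epoch: int = 300,
                 batch_size: int = 2, learning_rate: float = 1e-5,
                 max_track_shift: int = 5, seed: int = 0):
        self.depth = depth
        self.base_filters = base_filters
        self.epochs = epochs
        self.steps_per_epoch = steps_per_epoch
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.max_track_shift = max_track_shift
        self.seed = seed

    def _sample_stream(self, X, y, w, rng) -> Iterator:
        n = X.shape[0]
        while True:
            i = int(rng.integers(n))
            planes = {
                "prev_phase": X[i, 0], "prev_seed": X[i, 1],
                "curr_phase": X[i, 2], "curr_all_cells": X[i, 3],
                "target": y[i], "weights": w[i],
            }
            shifted, _ = aug.shift_current_frame(planes, self.max_track_shift,
                                                 rng)
            x = np.stack([shifted["prev_phase"], shifted["prev_seed"],
                          shifted["curr_phase"], shifted["curr_all_cells"]])
            yield x, shifted["target"], np.maximum(shifted["weights"], 1e-3)

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 4 or X.shape[1] != 4:
            raise ValueError("X must be (n_samples, 4, h, w)")
        if y.shape != (X.shape[0],) + X.shape[2:]:
            raise ValueError("y must be (n_samples, h, w)")
        w = (np.ones_like(y) if sample_weight is None
             else np.asarray(sample_weight, dtype=np.float64))
        rng = np.random.default_rng(self.seed)
        self.model_ = build_model(self._spec(in_planes=4))
        result = train(
            self.model_, self._sample_stream(X, y, w, rng),
            epochs=self.epochs, steps_per_epoch=self.steps_per_epoch,
            batch_size=self.batch_size, learning_rate=self.learning_rate,
        )
        self.loss_history_ = result.loss_history
        self.epoch_losses_ = result.epoch_losses
        self.n_iter_ = len(result.loss_history)
        return self

    def fit_stream(self, samples: Iterator, steps: int):
        """Train directly on a sample generator (x, target, weights) —
        used by the pipeline, which builds samples straight from a movie."""
        self.model_ = build_model(self._spec(in_planes=4))
        result = train(
            self.model_, samples, epochs=1, steps_per_epoch=steps,
            batch_size=self.batch_size, learning_rate=self.learning_rate,
        )
        self.loss_history_ = result.loss_history
        self.epoch_losses_ = result.epoch_losses
        self.n_iter_ = len(result.loss_history)
        return self

    def predict(self, X) -> np.ndarray:
        """Probability plane(s) for one (4, h, w) sample or a batch."""
        self._check_fitted()
        return self.model_.predict(np.asarray(X, dtype=np.float64))
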