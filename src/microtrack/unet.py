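"""Configurable U-Net encoder-decoder.

One architecture serves both models: the segmentation net maps a single
phase-contrast plane to a cell-probability plane, the tracking net maps the
four stacked tracking planes to a target-cell probability plane.  Depth
(number of 2x down-samplings) and the base filter count are configurable so
reduced variants (fewer levels / filters) can trade accuracy for speed; the
default profile is depth 4 with 64 base filters, the desk-scale profile
used throughout the test-suite is depth 3 with 16 filters.

Up-sampling is 2x nearest-neighbour followed by a 3x3 convolution (avoids
checkerboard artifacts of transposed convolutions); skip connections are
channel concatenations; the head is a 1x1 convolution with a sigmoid, so
outputs are probabilities in (0, 1) at the input resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterator

import numpy as np

from . import nn
from .losses import weighted_bce
from .weights import apply_variable_background

__all__ = ["UNetSpec", "UNet", "build_model", "train", "TrainResult"]


@dataclass
class UNetSpec:
    in_planes: int = 1
    depth: int = 4
    base_filters: int = 64
    seed: int = 0
    dtype: str = "float32"   # "float64" for gradient checks

    def filters(self, level: int) -> int:
        return self.base_filters * 2 ** level


class UNet:
    """U-Net with explicit forward/backward passes (see module docstring).

    Parameters live in ``self.params`` (name -> array); ``n_parameters`` is
    a deterministic function of the spec.
    """

    def __init__(self, spec: UNetSpec):
        if spec.depth < 1:
            raise ValueError("depth must be >= 1")
        self.spec = spec
        self.dtype = np.dtype(spec.dtype)
        rng = np.random.default_rng(spec.seed)
        self.params: dict[str, np.ndarray] = {}
        d, f = spec.depth, spec.base_filters
        c_prev = spec.in_planes
        for i in range(d):
            ci = spec.filters(i)
            self._add_conv(rng, f"e{i}a", ci, c_prev)
            self._add_conv(rng, f"e{i}b", ci, ci)
            c_prev = ci
        cb = spec.filters(d)
        self._add_conv(rng, "ba", cb, c_prev)
        self._add_conv(rng, "bb", cb, cb)
        for i in reversed(range(d)):
            ci = spec.filters(i)
            self._add_conv(rng, f"u{i}", ci, spec.filters(i + 1))
            self._add_conv(rng, f"d{i}a", ci, 2 * ci)
            self._add_conv(rng, f"d{i}b", ci, ci)
        self.params["head_w"] = nn.he_init(rng, 1, f, 1, self.dtype)
        self.params["head_b"] = np.zeros(1, dtype=self.dtype)
        self._cache: dict = {}

    def _add_conv(self, rng, name: str, c_out: int, c_in: int) -> None:
        self.params[f"{name}_w"] = nn.he_init(rng, c_out, c_in, 3, self.dtype)
        self.params[f"{name}_b"] = np.zeros(c_out, dtype=self.dtype)

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    # -- forward / backward -------------------------------------------------

    def _conv_relu(self, x, name):
        z, cols = nn.conv3x3(x, self.params[f"{name}_w"],
                             self.params[f"{name}_b"])
        self._cache[name] = (cols, z)
        return nn.relu(z)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, C_in, H, W) -> probabilities (N, 1, H, W).

        H and W are reflect-padded to a multiple of 2^depth and the output
        cropped back.
        """
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[None]
        n, c, h, w = x.shape
        if c != self.spec.in_planes:
            raise ValueError(f"expected {self.spec.in_planes} input planes, "
                             f"got {c}")
        m = 2 ** self.spec.depth
        ph, pw = (-h) % m, (-w) % m
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
        self._cache = {"pad": (h, w)}
        d = self.spec.depth
        skips = []
        for i in range(d):
            x = self._conv_relu(x, f"e{i}a")
            x = self._conv_relu(x, f"e{i}b")
            skips.append(x)
            x, pre = nn.maxpool2(x)
            self._cache[f"pool{i}"] = pre
        x = self._conv_relu(x, "ba")
        x = self._conv_relu(x, "bb")
        for i in reversed(range(d)):
            x = nn.upsample2(x)
            x = self._conv_relu(x, f"u{i}")
            self._cache[f"skipc{i}"] = x.shape[1]
            x = np.concatenate([skips[i], x], axis=1)
            x = self._conv_relu(x, f"d{i}a")
            x = self._conv_relu(x, f"d{i}b")
        z, cols = nn.conv1x1(x, self.params["head_w"], self.params["head_b"])
        self._cache["head"] = cols
        self._cache["logits_shape"] = z.shape
        p = nn.sigmoid(z.astype(np.float64))
        return p[:, :, :h, :w]

    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of all parameters given dLoss/dlogits (cropped shape).

        Combine with the sigmoid head analytically: for the weighted BCE,
        dLoss/dlogit = w * (p - gt) / sum(w).
        """
        h, w = self._cache["pad"]
        full = np.zeros(self._cache["logits_shape"], dtype=self.dtype)
        full[:, :, :h, :w] = dlogits
        grads: dict[str, np.ndarray] = {}

        def conv_back(g, name, c_in):
            cols, z = self._cache[name]
            g = nn.relu_backward(g, z) if name != "__head__" else g
            dx, dw, db = nn.conv3x3_backward(g, cols, self.params[f"{name}_w"],
                                             c_in)
            grads[f"{name}_w"] = dw
            grads[f"{name}_b"] = db
            return dx

        g, dw, db = nn.conv1x1_backward(full, self._cache["head"],
                                        self.params["head_w"])
        grads["head_w"] = dw
        grads["head_b"] = db

        d, f = self.spec.depth, self.spec.base_filters
        spec = self.spec
        skip_grads: dict[int, np.ndarray] = {}
        for i in range(d):
            ci = spec.filters(i)
            g = conv_back(g, f"d{i}b", ci)
            g = conv_back(g, f"d{i}a", 2 * ci)
            upc = self._cache[f"skipc{i}"]
            skip_grads[i] = g[:, :-upc]
            g = conv_back(g[:, -upc:], f"u{i}", spec.filters(i + 1))
            g = nn.upsample2_backward(g)
        g = conv_back(g, "bb", spec.filters(d))
        g = conv_back(g, "ba", spec.filters(d - 1))
        for i in reversed(range(d)):
            g = nn.maxpool2_backward(g, self._cache[f"pool{i}"])
            g = g + skip_grads[i]
            ci = spec.filters(i)
            g = conv_back(g, f"e{i}b", ci)
            g = conv_back(g, f"e{i}a",
                          spec.in_planes if i == 0 else spec.filters(i - 1))
        return grads

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Probability plane(s) for (H, W), (C, H, W) or (N, C, H, W) input."""
        x = np.asarray(x)
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None]
        single = x.ndim == 3
        p = self.forward(x[None] if single else x)
        p = p[:, 0]
        return p[0] if (single or squeeze) else p

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(path, __spec__=np.array(
            [self.spec.in_planes, self.spec.depth, self.spec.base_filters,
             self.spec.seed]),
            __dtype__=np.array(str(self.spec.dtype)), **self.params)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        with np.load(path, allow_pickle=False) as data:
            ip, d, f, seed = (int(v) for v in data["__spec__"])
            spec = UNetSpec(in_planes=ip, depth=d, base_filters=f, seed=seed,
                            dtype=str(data["__dtype__"]))
            model = cls(spec)
            for k in model.params:
                model.params[k] = data[k]
        return model


def build_model(spec: UNetSpec) -> UNet:
    """Build an untrained U-Net from its spec."""
    return UNet(spec)


@dataclass
class TrainResult:
    loss_history: list          # per-step losses
    epoch_losses: list          # per-epoch means
    checkpoint_epochs: list     # epochs where the loss reached a new minimum
    best_loss: float


def train(
    model: UNet,
    samples: Iterator[tuple[np.ndarray, np.ndarray, np.ndarray]],
    *,
    epochs: int = 1,
    steps_per_epoch: int = 300,
    batch_size: int = 1,
    learning_rate: float = 1e-4,
    variable_background: bool = False,
    backgrounds: Callable[[np.ndarray], np.ndarray] | None = None,
    checkpoint: str | Path | None = None,
) -> TrainResult:
    """Train with Adam on a stream of (input, gt, weight-map) samples.

    ``samples`` yields ``x`` of shape (C, H, W), a binary ``gt`` (H, W) and
    a weight map (H, W).  With ``variable_background`` the background part
    of each weight map is replaced by the model's current prediction before
    the gradient is taken; ``backgrounds(gt)`` may supply the background
    mask (default: ``gt == 0``).  A checkpoint is written only when an
    epoch's mean loss reaches a new minimum.  A NaN loss aborts with a
    diagnostic.
    """
    opt = nn.Adam(lr=learning_rate)
    history: list[float] = []
    epoch_losses: list[float] = []
    checkpoint_epochs: list[int] = []
    best = np.inf
    for epoch in range(epochs):
        losses = []
        for _ in range(steps_per_epoch):
            batch = [next(samples) for _ in range(batch_size)]
            x = np.stack([b[0] for b in batch]).astype(model.dtype)
            gt = np.stack([b[1] for b in batch]).astype(np.float64)
            wm = np.stack([b[2] for b in batch]).astype(np.float64)
            p = model.forward(x)[:, 0]
            if variable_background:
                wm = np.stack([
                    apply_variable_background(
                        wm[i], np.clip(p[i], 0.0, 1.0),
                        gt[i] if backgrounds is None else backgrounds(gt[i]))
                    for i in range(len(batch))])
            loss = float(np.mean([weighted_bce(gt[i], p[i], wm[i])
                                  for i in range(len(batch))]))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {loss}; "
                    "lower the learning rate or check the weight maps")
            history.append(loss)
            losses.append(loss)
            dlogit = (wm * (p - gt) / wm.sum(axis=(1, 2), keepdims=True)
                      / len(batch))[:, None]
            grads = model.backward(dlogit.astype(model.dtype))
            opt.step(model.params, grads)
        mean_loss = float(np.mean(losses))
        epoch_losses.append(mean_loss)
        if mean_loss < best:
            best = mean_loss
            checkpoint_epochs.append(epoch)
            if checkpoint is not None:
                model.save(checkpoint)
    return TrainResult(loss_history=history, epoch_losses=epoch_losses,
                       checkpoint_epochs=checkpoint_epochs, best_loss=best)
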