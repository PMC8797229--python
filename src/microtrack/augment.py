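"""Training-time data augmentation.

Geometric operations (random shift, scale, rotation, flips, illumination)
plus three augmentations aimed at microscopy failure modes: Gaussian blur
(out-of-focus frames), additive Gaussian sensor noise, and an inter-frame
shift that translates only the current-frame planes of a tracking sample to
emulate stage drift between timepoints.

Order of application is geometric -> blur -> noise.  Images use bilinear
interpolation, masks and weight maps nearest-neighbour so labels stay
integral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "AugmentConfig",
    "gaussian_kernel5",
    "gaussian_blur",
    "add_noise",
    "int_shift",
    "shift_current_frame",
    "random_geometric",
    "random_illumination",
]


@dataclass
class AugmentConfig:
    sigma_blur: float = 1.0
    sigma_noise: float = 0.03
    max_track_shift: int = 5      # px, current-frame planes only
    max_shift: int = 30           # px, whole-sample geometric shift
    scale_range: tuple[float, float] = (0.9, 1.1)
    rotation_deg: float = 180.0
    flip: bool = True
    gamma_range: tuple[float, float] = (0.7, 1.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_blur < 0 or self.sigma_noise < 0:
            raise ValueError("sigmas must be >= 0")
        if self.max_track_shift < 0 or self.max_shift < 0:
            raise ValueError("shift ranges must be >= 0")


def gaussian_kernel5(sigma: float) -> np.ndarray:
    """The 5x5 truncated, normalised Gaussian kernel with std ``sigma``."""
    x = np.arange(-2, 3, dtype=np.float64)
    k1 = np.exp(-(x**2) / (2.0 * sigma**2))
    k = np.outer(k1, k1)
    return k / k.sum()


def gaussian_blur(image: np.ndarray, sigma: float) -> np.ndarray:
    """Convolve a 5x5 Gaussian kernel over the image (reflect padding).

    ``sigma = 0`` is the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return np.asarray(image, dtype=np.float64).copy()
    k = gaussian_kernel5(sigma)
    return ndimage.correlate(np.asarray(image, dtype=np.float64), k,
                             mode="reflect")


def add_noise(image: np.ndarray, sigma: float,
              rng: np.random.Generator | None = None) -> np.ndarray:
    """Add per-pixel N(0, sigma^2) noise, then min-max rescale to [0, 1].

    The rescale runs even for ``sigma = 0``, so a noiseless non-constant
    image still comes out with min 0 and max 1; a constant result maps to
    zeros.
    """
    rng = rng or np.random.default_rng()
    image = np.asarray(image, dtype=np.float64)
    out = image + rng.normal(0.0, sigma, image.shape) if sigma > 0 else image
    lo, hi = out.min(), out.max()
    if hi <= lo:
        return np.zeros_like(out)
    return (out - lo) / (hi - lo)


def int_shift(arr: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer translation with zero fill of the vacated pixels."""
    out = np.zeros_like(arr)
    H, W = arr.shape[-2:]
    ys = slice(max(dy, 0), H + min(dy, 0))
    xs = slice(max(dx, 0), W + min(dx, 0))
    ys_src = slice(max(-dy, 0), H + min(-dy, 0))
    xs_src = slice(max(-dx, 0), W + min(-dx, 0))
    out[..., ys, xs] = arr[..., ys_src, xs_src]
    return out


def shift_current_frame(
    planes: dict[str, np.ndarray],
    max_shift: int,
    rng: np.random.Generator,
    current_keys: tuple[str, ...] = ("curr_phase", "curr_all_cells",
                                     "target", "weights"),
) -> tuple[dict[str, np.ndarray], tuple[int, int]]:
    """Shift the current-frame planes of a tracking sample by one common
    integer vector drawn uniformly from [-max_shift, max_shift]^2.

    Previous-frame planes are untouched; vacated pixels are zero-filled.
    Returns the shifted planes and the applied (dy, dx).
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    dy = int(rng.integers(-max_shift, max_shift + 1)) if max_shift else 0
    dx = int(rng.integers(-max_shift, max_shift + 1)) if max_shift else 0
    out = {}
    for key, arr in planes.items():
        out[key] = int_shift(arr, dy, dx) if key in current_keys else arr.copy()
    return out, (dy, dx)


def random_illumination(image: np.ndarray, cfg: AugmentConfig,
                        rng: np.random.Generator) -> np.ndarray:
    gamma = rng.uniform(*cfg.gamma_range)
    return np.clip(image, 0.0, 1.0) ** gamma


def random_geometric(
    images: list[np.ndarray],
    masks: list[np.ndarray],
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """One random shift/scale/rotation/flip applied identically to every
    plane; bilinear for images, nearest for masks/weight maps."""
    shape = images[0].shape if images else masks[0].shape
    H, W = shape
    angle = np.deg2rad(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
    scale = rng.uniform(*cfg.scale_range)
    dy = rng.uniform(-cfg.max_shift, cfg.max_shift)
    dx = rng.uniform(-cfg.max_shift, cfg.max_shift)
    flip_y = cfg.flip and rng.random() < 0.5
    flip_x = cfg.flip and rng.random() < 0.5

    c, s = np.cos(angle), np.sin(angle)
    lin = np.array([[c, -s], [s, c]]) / scale
    if flip_y:
        lin = lin @ np.diag([-1.0, 1.0])
    if flip_x:
        lin = lin @ np.diag([1.0, -1.0])
    center = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
    offset = center - lin @ (center + np.array([dy, dx]))

    def warp(arr: np.ndarray, order: int) -> np.ndarray:
        return ndimage.affine_transform(arr.astype(np.float64), lin,
                                        offset=offset, order=order,
                                        mode="constant", cval=0.0,
                                        prefilter=False)

    out_images = [warp(im, 1) for im in images]
    out_masks = []
    for m in masks:
        warped = warp(m, 0)
        out_masks.append(warped.astype(m.dtype) if np.issubdtype(
            m.dtype, np.integer) else warped)
    return out_images, out_masks
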