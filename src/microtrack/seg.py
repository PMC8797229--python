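"""Whole-frame segmentation: tile large frames, predict, stitch, label.

Frames larger than the model window (default 512x512) are cropped into
overlapping windows, each window is segmented separately, and the outputs
are blended back together with weights that taper linearly to zero at
window edges inside the overlap zone.  The blend is written as
"reference + weighted deviation from the reference", which makes stitching
bit-exact whenever all windows agree (e.g. for an identity operation).

The probability plane is thresholded at 0.5 and labelled by plain connected
components — the network is trained (through the weight maps) to output low
probability at inter-cell interfaces, so no watershed or other ad hoc
post-processing is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label

from .io import LabelMask, Movie, normalize_frame

__all__ = ["TileLayout", "tile", "stitch", "segment_frame", "segment_movie"]


@dataclass
class TileLayout:
    """Half-open windows covering a (H, W) frame.

    A frame no larger than the window is covered by a single full-frame
    window (no tiling)."""

    shape: tuple[int, int]
    window: tuple[int, int] = (512, 512)
    overlap: int = 128
    boxes: list[tuple[int, int, int, int]] = field(init=False)

    def __post_init__(self) -> None:
        H, W = self.shape
        wh = min(self.window[0], H)
        ww = min(self.window[1], W)
        rows = _starts(H, wh, self.overlap)
        cols = _starts(W, ww, self.overlap)
        self.boxes = [(r, r + wh, c, c + ww) for r in rows for c in cols]

    def __len__(self) -> int:
        return len(self.boxes)


def _starts(size: int, window: int, overlap: int) -> list[int]:
    if window >= size:
        return [0]
    stride = max(window - overlap, 1)
    starts = list(range(0, size - window, stride))
    starts.append(size - window)
    return sorted(set(starts))


def tile(image: np.ndarray, layout: TileLayout) -> list[np.ndarray]:
    return [image[r0:r1, c0:c1] for r0, r1, c0, c1 in layout.boxes]


def _taper(n: int, at_start: bool, at_end: bool, overlap: int) -> np.ndarray:
    w = np.ones(n)
    ramp_len = min(max(overlap, 1), n)
    ramp = (np.arange(1, ramp_len + 1)) / float(ramp_len)
    if at_start:  # interior edge at the start of the axis
        w[:ramp_len] = ramp
    if at_end:
        w[-ramp_len:] = np.minimum(w[-ramp_len:], ramp[::-1])
    return w


def stitch(windows: list[np.ndarray], layout: TileLayout) -> np.ndarray:
    """Blend per-window outputs back to a full frame.

    Each pixel is a weighted average of the contributing windows; window
    weights taper linearly to 0 at interior window edges within the overlap
    zone (edges flush with the frame border keep full weight).  Implemented
    as reference + sum(w * (x - ref)) / sum(w), so identical contributions
    reproduce the reference bit-for-bit.
    """
    H, W = layout.shape
    if len(windows) != len(layout.boxes):
        raise ValueError("window count does not match the layout")
    if len(windows) == 1:
        out = np.empty((H, W), dtype=np.float64)
        out[:] = windows[0]
        return out
    ref = np.zeros((H, W))
    for win, (r0, r1, c0, c1) in zip(windows, layout.boxes):
        ref[r0:r1, c0:c1] = win
    num = np.zeros((H, W))
    den = np.zeros((H, W))
    for win, (r0, r1, c0, c1) in zip(windows, layout.boxes):
        wr = _taper(r1 - r0, r0 > 0, r1 < H, layout.overlap)
        wc = _taper(c1 - c0, c0 > 0, c1 < W, layout.overlap)
        w2 = np.outer(wr, wc)
        num[r0:r1, c0:c1] += w2 * (win - ref[r0:r1, c0:c1])
        den[r0:r1, c0:c1] += w2
    return ref + num / den


def segment_frame(
    frame: np.ndarray,
    model,
    *,
    threshold: float = 0.5,
    min_area: int = 20,
    window: tuple[int, int] = (512, 512),
    overlap: int = 128,
    connectivity: int = 2,
    return_proba: bool = False,
):
    """Segment one normalised phase-contrast frame into a label image.

    ``model`` is anything with ``predict(image) -> probability plane``.
    Frames larger than ``window`` are tiled and stitched.
    """
    frame = np.asarray(frame, dtype=np.float64)
    layout = TileLayout(shape=frame.shape, window=window, overlap=overlap)
    if len(layout) == 1:
        proba = np.asarray(model.predict(frame), dtype=np.float64)
    else:
        outs = [np.asarray(model.predict(win), dtype=np.float64)
                for win in tile(frame, layout)]
        proba = stitch(outs, layout)
    binary = proba > threshold
    labels = cc_label(binary, connectivity=connectivity).astype(np.int32)
    if min_area > 1 and labels.max() > 0:
        sizes = np.bincount(labels.ravel())
        keep = np.flatnonzero(sizes >= min_area)
        keep = keep[keep > 0]
        remap = np.zeros(len(sizes), dtype=np.int32)
        remap[keep] = np.arange(1, len(keep) + 1)
        labels = remap[labels]
    return (labels, proba) if return_proba else labels


def segment_movie(
    movie: Movie,
    model,
    *,
    lo_pct: float = 0.1,
    hi_pct: float = 99.9,
    **kwargs,
) -> LabelMask:
    """Normalise and segment every frame of a movie."""
    frames = [
        segment_frame(normalize_frame(movie.phase(t), lo_pct, hi_pct),
                      model, **kwargs)
        for t in range(movie.n_frames)
    ]
    return LabelMask(frames=frames, connectivity=kwargs.get("connectivity", 2))
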