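"""Reading and writing movies, label masks and result tables.

Movies come in as TIFF sequences (one file per frame/channel, ordered by a
numbered filename pattern) or as single multi-page / OME-TIFF stacks.
Results go out as 16-bit TIFF label masks, a flat CSV of per-(cell, frame)
observations, and a MAT-v5 container mirroring the same table for users who
post-process in Matlab.

Conventions used throughout the package: 0-based row-major (row, col)
coordinates with the origin at the top-left; all crop windows are half-open
``[r0, r1) x [c0, c1)`` intervals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
from scipy.io import savemat

__all__ = [
    "Movie",
    "LabelMask",
    "read_movie",
    "write_movie",
    "normalize_frame",
    "write_results",
    "read_mask_sequence",
    "write_mask_sequence",
]


@dataclass
class Movie:
    """A time-lapse stack: ``data[channel]`` is a (frames, H, W) float array.

    Exactly one channel is designated the phase-contrast channel.  The frame
    interval is in minutes and the pixel size in micrometres per pixel
    (optional; ``None`` when the source carries no calibration).
    """

    data: dict[str, np.ndarray]
    phase_channel: str = "phase"
    interval_min: float = 5.0
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        if self.phase_channel not in self.data:
            raise ValueError(
                f"phase channel {self.phase_channel!r} not among channels "
                f"{sorted(self.data)}"
            )
        shapes = {ch: arr.shape for ch, arr in self.data.items()}
        ref = next(iter(shapes.values()))
        if any(s != ref for s in shapes.values()):
            raise ValueError(f"channels disagree on shape: {shapes}")

    @property
    def n_frames(self) -> int:
        return self.data[self.phase_channel].shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data[self.phase_channel].shape[1:]

    @property
    def channels(self) -> list[str]:
        return list(self.data)

    def phase(self, t: int) -> np.ndarray:
        return self.data[self.phase_channel][t]

    def channel(self, name: str, t: int) -> np.ndarray:
        return self.data[name][t]


@dataclass
class LabelMask:
    """Per-frame integer label images: 0 = background, >=1 = cells.

    ``connectivity`` records the component convention (1 = 4-connected,
    2 = 8-connected) so that evaluation uses the same setting.
    """

    frames: list[np.ndarray] = field(default_factory=list)
    connectivity: int = 2

    def __post_init__(self) -> None:
        self.frames = [np.asarray(f, dtype=np.int32) for f in self.frames]

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, t: int) -> np.ndarray:
        return self.frames[t]

    def labels(self, t: int) -> np.ndarray:
        lab = np.unique(self.frames[t])
        return lab[lab > 0]


_FRAME_RE = re.compile(r"(\d+)\D*$")


def _frame_index(path: Path) -> int:
    m = _FRAME_RE.search(path.stem)
    if m is None:
        raise ValueError(f"cannot parse a frame number from {path.name!r}")
    return int(m.group(1))


def read_movie(
    path: str | Path,
    channel_spec: Mapping[str, int | str] | None = None,
    *,
    phase_channel: str = "phase",
    interval_min: float = 5.0,
    pixel_size_um: float | None = None,
) -> Movie:
    """Read a movie from a TIFF sequence directory or a multi-page TIFF.

    For a directory, ``channel_spec`` maps channel names to filename
    substrings (e.g. ``{"phase": "pha", "gfp": "gfp"}``); files within a
    channel are ordered by the trailing number in their stem and a gap in the
    numbering is an error.  For a single file, ``channel_spec`` maps channel
    names to plane indices along the channel axis (a plain (T, H, W) stack is
    a single phase channel).  Intensities are returned raw, as stored.
    """
    path = Path(path)
    if path.is_dir():
        data = _read_sequence_dir(path, channel_spec or {phase_channel: ""})
    else:
        data = _read_stack_file(path, channel_spec, phase_channel)
    return Movie(
        data=data,
        phase_channel=phase_channel,
        interval_min=interval_min,
        pixel_size_um=pixel_size_um,
    )


def _read_sequence_dir(
    path: Path, channel_spec: Mapping[str, int | str]
) -> dict[str, np.ndarray]:
    data: dict[str, np.ndarray] = {}
    for ch, pattern in channel_spec.items():
        files = sorted(
            (p for p in path.iterdir()
             if p.suffix.lower() in (".tif", ".tiff") and str(pattern) in p.stem),
            key=_frame_index,
        )
        if not files:
            raise FileNotFoundError(
                f"no TIFF files matching {pattern!r} for channel {ch!r} in {path}"
            )
        indices = [_frame_index(p) for p in files]
        expected = list(range(indices[0], indices[0] + len(indices)))
        if indices != expected:
            missing = sorted(set(expected) - set(indices))
            raise ValueError(
                f"channel {ch!r}: missing frame number(s) {missing} in {path}"
            )
        frames = [tifffile.imread(p) for p in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"channel {ch!r}: inconsistent frame shapes {shapes}")
        data[ch] = np.stack([np.asarray(f, dtype=np.float64) for f in frames])
    shapes = {arr.shape[1:] for arr in data.values()}
    if len(shapes) != 1:
        raise ValueError(f"channels disagree on frame shape: {shapes}")
    return data


def _read_stack_file(
    path: Path,
    channel_spec: Mapping[str, int | str] | None,
    phase_channel: str,
) -> dict[str, np.ndarray]:
    arr = tifffile.imread(path)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 3:
        return {phase_channel: arr}
    if arr.ndim == 4:  # (T, C, H, W)
        n_ch = arr.shape[1]
        if channel_spec is None:
            channel_spec = {phase_channel: 0}
            channel_spec.update({f"ch{i}": i for i in range(1, n_ch)})
        return {ch: arr[:, int(idx) if str(idx).strip() else 0]
                for ch, idx in channel_spec.items()}
    raise ValueError(f"unsupported TIFF dimensionality {arr.shape} in {path}")


def write_movie(movie: Movie, path: str | Path) -> Path:
    """Write a movie as one multi-page OME-TIFF (axes TCYX, float32)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stack = np.stack([movie.data[ch] for ch in movie.channels], axis=1)
    tifffile.imwrite(path, stack.astype(np.float32), ome=True,
                     metadata={"axes": "TCYX"})
    return path


def normalize_frame(
    image: np.ndarray, lo_pct: float = 0.1, hi_pct: float = 99.9
) -> np.ndarray:
    """Percentile-clipped min-max scaling of a frame into [0, 1].

    Values below the ``lo_pct`` percentile map to 0 and values above the
    ``hi_pct`` percentile map to 1, which keeps hot pixels from compressing
    the dynamic range.  A constant image maps to all zeros.  Percentiles are
    taken as order statistics (no interpolation), which makes the operation
    exactly idempotent.
    """
    if hi_pct <= lo_pct:
        raise ValueError(f"hi_pct must exceed lo_pct, got {lo_pct}, {hi_pct}")
    image = np.asarray(image, dtype=np.float64)
    lo = np.percentile(image, lo_pct, method="lower")
    hi = np.percentile(image, hi_pct, method="higher")
    if hi <= lo:
        return np.zeros_like(image)
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


def write_mask_sequence(masks: LabelMask, out_dir: str | Path,
                        prefix: str = "mask") -> list[Path]:
    """Write each frame's label image as a 16-bit TIFF."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t, frame in enumerate(masks.frames):
        if frame.max() > np.iinfo(np.uint16).max:
            raise ValueError(f"frame {t}: label exceeds 16-bit range")
        p = out_dir / f"{prefix}_t{t:04d}.tif"
        tifffile.imwrite(p, frame.astype(np.uint16))
        paths.append(p)
    return paths


def read_mask_sequence(path: str | Path, pattern: str = "mask") -> LabelMask:
    files = sorted(
        (p for p in Path(path).iterdir()
         if p.suffix.lower() in (".tif", ".tiff") and pattern in p.stem),
        key=_frame_index,
    )
    if not files:
        raise FileNotFoundError(f"no mask TIFFs matching {pattern!r} in {path}")
    return LabelMask(frames=[tifffile.imread(p).astype(np.int32) for p in files])


def write_results(
    lineage: pd.DataFrame,
    masks: LabelMask,
    features: pd.DataFrame,
    path: str | Path,
) -> dict[str, Path]:
    """Write the standard result bundle.

    Emits (a) the label-mask image sequence as 16-bit TIFFs, (b)
    ``lineage.csv`` (one row per cell) and ``features.csv`` (one row per
    (cell, frame) observation), and (c) ``results.mat``, a MAT-v5 container
    mirroring both tables column-by-column.

    Every ``cell_id`` referenced in ``features`` must exist in ``lineage``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if len(features) and len(lineage):
        missing = set(features["cell_id"]) - set(lineage["cell_id"])
        if missing:
            raise ValueError(f"features reference unknown cell ids: {sorted(missing)}")
    elif len(features):
        raise ValueError("features reference cells but the lineage table is empty")

    out: dict[str, Path] = {}
    write_mask_sequence(masks, path / "masks")
    out["masks"] = path / "masks"
    out["lineage"] = path / "lineage.csv"
    lineage.to_csv(out["lineage"], index=False)
    out["features"] = path / "features.csv"
    features.to_csv(out["features"], index=False)
    out["mat"] = path / "results.mat"
    savemat(out["mat"], {
        "lineage": _frame_to_mat(lineage),
        "features": _frame_to_mat(features),
    })
    return out


def _frame_to_mat(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Column dict for MAT export; object columns become string arrays."""
    mat: dict[str, np.ndarray] = {}
    for col in df.columns:
        s = df[col]
        if s.dtype == object or str(s.dtype).startswith("str"):
            mat[col] = np.asarray(["" if v is None or v != v else str(v)
                                   for v in s], dtype=object)
        else:
            mat[col] = s.to_numpy()
    return mat
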