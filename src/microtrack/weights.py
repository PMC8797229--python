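"""Training targets and per-pixel loss weight maps.

Both networks train against a pixelwise-weighted binary cross-entropy, so
each ground-truth plane is paired with a nonnegative weight map that decides
how much each pixel contributes to the loss.  For segmentation the maps
emphasise what matters for separating touching rods: the morphological
skeleton of every cell carries the highest cell weight, the skeleton of the
inter-cell border region carries the highest weight overall, the one-pixel
contact ring between a cell and a border region is strongly de-emphasised
(those interfaces are arbitrary at pixel resolution), and plain background
gets a small base weight.  Background weights can additionally be made
*variable*: replaced by the model's own prediction so that confidently wrong
background pixels (debris predicted as cells) are punished hard while
correctly ignored background stays cheap.

For tracking, the target cell's skeleton gets the maximum weight and every
other cell's pixels decay with their Euclidean distance from the target, so
nearby distractors matter more than distant ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

__all__ = [
    "WeightParams",
    "SegTarget",
    "seg_gt_and_border",
    "make_seg_weightmap",
    "make_seg_target",
    "apply_variable_background",
    "make_track_target",
]


@dataclass
class WeightParams:
    """Weight-map parameters (all configurable; defaults reproduce the
    qualitative ordering cell-skeleton < border-skeleton, interface lowest).

    w_skeleton: weight on cell skeletons (and the tracking target skeleton).
    w_border_skeleton: weight on skeletons of inter-cell border regions.
    w_interface: weight on the 1-px cell/border contact ring.
    w_background_base: weight on plain background.
    d_border_px: a background pixel within this distance of >= 2 distinct
        cells belongs to the border region.
    track_decay_px: e-folding length of the distance decay applied to
        non-target cells in tracking weight maps.
    """

    w_skeleton: float = 4.0
    w_border_skeleton: float = 8.0
    w_interface: float = 0.25
    w_background_base: float = 0.1
    d_border_px: float = 2.0
    track_decay_px: float = 32.0


@dataclass
class SegTarget:
    """Binary ground truth (cell interiors, eroded where cells touch),
    the inter-cell border plane, and the paired weight map."""

    gt: np.ndarray
    border: np.ndarray
    weights: np.ndarray


def _touching_ring(labels: np.ndarray) -> np.ndarray:
    """Cell pixels 8-adjacent to a *different* positive label."""
    big = np.iinfo(np.int32).max
    maxf = ndimage.maximum_filter(labels, size=3)
    pos = np.where(labels > 0, labels, big)
    minf = ndimage.minimum_filter(pos, size=3)
    cell = labels > 0
    return cell & ((maxf > labels) | (minf < labels))


def _border_region(labels: np.ndarray, d_border: float) -> np.ndarray:
    """Background pixels within ``d_border`` of >= 2 distinct labels."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if len(ids) < 2:
        return np.zeros(labels.shape, dtype=bool)
    count = np.zeros(labels.shape, dtype=np.int16)
    for lab in ids:
        d = ndimage.distance_transform_edt(labels != lab)
        count += d <= d_border
    return (count >= 2) & (labels == 0)


def seg_gt_and_border(labels: np.ndarray,
                      params: WeightParams | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Binary GT plane and border plane from a labelled frame.

    The GT is each cell's footprint eroded by one pixel wherever two labels
    touch, so the binary target never fuses neighbours; the border plane is
    the inter-cell border region.  The two planes are disjoint.
    """
    params = params or WeightParams()
    labels = np.asarray(labels)
    gt = (labels > 0) & ~_touching_ring(labels)
    border = _border_region(labels, params.d_border_px)
    return gt, border


def make_seg_weightmap(labels: np.ndarray,
                       params: WeightParams | None = None) -> np.ndarray:
    """Segmentation weight map for one labelled frame.

    Per-pixel weights: cell bodies ramp from 1 at the boundary up to
    ``w_skeleton`` on each cell's skeleton; border regions ramp from 1 up to
    ``w_border_skeleton`` on the border skeleton; the 1-px cell/border
    contact ring gets ``w_interface``; everything else gets
    ``w_background_base``.  An empty frame yields a uniform background map.
    """
    params = params or WeightParams()
    labels = np.asarray(labels)
    wm = np.full(labels.shape, params.w_background_base, dtype=np.float64)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if len(ids) == 0:
        return wm

    # cell bodies: distance-to-boundary ramp strictly below the skeleton
    # weight (normalised by dmax + 1), skeleton forced to the max
    for lab in ids:
        mask = labels == lab
        edt = ndimage.distance_transform_edt(mask)
        wm[mask] = 1.0 + (params.w_skeleton - 1.0) * edt[mask] / (edt.max() + 1.0)
        skel = skeletonize(mask)
        wm[skel] = params.w_skeleton

    border = _border_region(labels, params.d_border_px)
    if border.any():
        edt = ndimage.distance_transform_edt(border)
        wm[border] = 1.0 + (params.w_border_skeleton - 1.0) * (
            edt[border] / (edt[border].max() + 1.0))
        bskel = skeletonize(border)
        wm[bskel] = params.w_border_skeleton

        # interface: cell pixels within 1 px of the border region
        near_border = ndimage.binary_dilation(border, structure=np.ones((3, 3)))
        wm[(labels > 0) & near_border] = params.w_interface
    # cells touching with no background gap between them: de-emphasise the
    # touching ring the same way
    wm[_touching_ring(labels)] = params.w_interface
    return wm


def make_seg_target(labels: np.ndarray,
                    params: WeightParams | None = None) -> SegTarget:
    params = params or WeightParams()
    gt, border = seg_gt_and_border(labels, params)
    return SegTarget(gt=gt, border=border,
                     weights=make_seg_weightmap(labels, params))


def apply_variable_background(
    weights: np.ndarray,
    prediction: np.ndarray,
    gt: np.ndarray,
    border: np.ndarray | None = None,
    params: WeightParams | None = None,
) -> np.ndarray:
    """Variable background weighting: on background pixels (not cell, not
    border) the weight becomes the model's own prediction plus the base
    floor; all other weights are untouched."""
    params = params or WeightParams()
    prediction = np.asarray(prediction, dtype=np.float64)
    if weights.shape != prediction.shape or weights.shape != np.shape(gt):
        raise ValueError("weights, prediction and gt must share a shape")
    if prediction.min() < 0.0 or prediction.max() > 1.0:
        raise ValueError("prediction values must lie in [0, 1]")
    bg = ~np.asarray(gt, dtype=bool)
    if border is not None:
        bg &= ~np.asarray(border, dtype=bool)
    out = weights.astype(np.float64).copy()
    out[bg] = prediction[bg] + params.w_background_base
    return out


def make_track_target(
    assigned_labels: tuple[int, ...] | list[int] | int,
    labels_current: np.ndarray,
    params: WeightParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Tracking target and weight map for one query cell.

    ``assigned_labels`` names the 1 (no division) or 2 (division) labels in
    the current frame that the query cell maps to.  The target is the union
    binary mask of those labels.  The weight map puts ``w_skeleton`` on the
    target's skeleton, 1 elsewhere on the target, a distance-decaying weight
    ``w_skeleton/2 * exp(-d / track_decay_px)`` (floored at the background
    base) on other cells, and the background base elsewhere.
    """
    params = params or WeightParams()
    if np.isscalar(assigned_labels):
        assigned_labels = (int(assigned_labels),)
    assigned = tuple(int(l) for l in assigned_labels)
    if not 1 <= len(assigned) <= 2:
        raise ValueError("a query maps to 1 or 2 current-frame labels")
    labels_current = np.asarray(labels_current)
    present = set(np.unique(labels_current)) - {0}
    missing = [l for l in assigned if l not in present]
    if missing:
        raise ValueError(f"assigned label(s) {missing} absent from frame")

    target = np.isin(labels_current, assigned)
    wm = np.full(labels_current.shape, params.w_background_base)
    d = ndimage.distance_transform_edt(~target)
    others = (labels_current > 0) & ~target
    wm[others] = np.maximum(
        0.5 * params.w_skeleton * np.exp(-d[others] / params.track_decay_px),
        params.w_background_base)
    wm[target] = 1.0
    for lab in assigned:
        wm[skeletonize(labels_current == lab)] = params.w_skeleton
    return target, wm
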