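"""Frame-to-frame tracking and lineage reconstruction.

For every cell in the previous frame a 4-plane sample is cropped around the
cell's previous centroid: previous phase image, binary mask of the query
cell, current phase image, and binary mask of all current cells.  The
tracking network (or an oracle predictor in tests) turns the sample into a
probability plane over the crop; each current-frame cell is then scored by
the mean predicted value over its pixels, and queries are resolved globally
into continuations, divisions (two daughters) or exits.  Unclaimed current
cells are orphans — cells that entered the field.

After a division the septum position decides pole ages: the daughters'
mutually nearest endpoints define the septum, each daughter's endpoint
nearest the septum is its new pole, and the daughter whose far endpoint
matches the mother's old pole appends 'O' to its history while its sibling
appends 'N'.  Founders have age-unknown poles; their first division
initialises pole tracking without appending a letter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import LabelMask, Movie, normalize_frame
from .lineage import cell_endpoints, cell_length, fluorescence
from .weights import WeightParams, make_track_target

__all__ = [
    "TrackingSample",
    "AssignmentResult",
    "build_sample",
    "score_and_assign",
    "detect_division_and_poles",
    "OraclePredictor",
    "ModelPredictor",
    "track_movie",
    "TrackResult",
    "make_training_samples",
]


@dataclass
class TrackingSample:
    """One query cell's 4-plane tracking input plus its crop geometry.

    ``crop_box`` is half-open (r0, r1, c0, c1) in frame coordinates; it is
    clamped inside the frame by shifting (never shrinking), so its size is
    ``min(crop, frame)`` in each axis.
    """

    prev_label: int
    crop_box: tuple[int, int, int, int]
    prev_phase: np.ndarray
    prev_seed: np.ndarray
    curr_phase: np.ndarray
    curr_all_cells: np.ndarray

    def stacked(self) -> np.ndarray:
        return np.stack([self.prev_phase, self.prev_seed.astype(np.float64),
                         self.curr_phase,
                         self.curr_all_cells.astype(np.float64)])


@dataclass
class AssignmentResult:
    prev_label: int
    scores: dict[int, float]
    outcome: tuple  # ("continues", lab) | ("divides", l1, l2) | ("exited", None)


def _clamped_box(center: tuple[float, float], crop: tuple[int, int],
                 shape: tuple[int, int]) -> tuple[int, int, int, int]:
    ch = min(crop[0], shape[0])
    cw = min(crop[1], shape[1])
    r0 = int(round(center[0])) - ch // 2
    c0 = int(round(center[1])) - cw // 2
    r0 = max(0, min(r0, shape[0] - ch))
    c0 = max(0, min(c0, shape[1] - cw))
    return r0, r0 + ch, c0, c0 + cw


def build_sample(
    prev_phase: np.ndarray,
    prev_labels: np.ndarray,
    curr_phase: np.ndarray,
    curr_labels: np.ndarray,
    prev_label: int,
    crop: tuple[int, int] = (256, 256),
) -> TrackingSample:
    """Crop the four tracking planes around the query cell's previous
    centroid (box clamped inside the frame by shifting)."""
    seed = prev_labels == prev_label
    if not seed.any():
        raise ValueError(f"label {prev_label} absent from the previous frame")
    center = ndimage.center_of_mass(seed)
    box = _clamped_box(center, crop, prev_labels.shape)
    r0, r1, c0, c1 = box
    return TrackingSample(
        prev_label=prev_label,
        crop_box=box,
        prev_phase=np.asarray(prev_phase, dtype=np.float64)[r0:r1, c0:c1],
        prev_seed=seed[r0:r1, c0:c1],
        curr_phase=np.asarray(curr_phase, dtype=np.float64)[r0:r1, c0:c1],
        curr_all_cells=(curr_labels > 0)[r0:r1, c0:c1],
    )


def score_and_assign(
    predictions: list[tuple[TrackingSample, np.ndarray]],
    curr_labels: np.ndarray,
    theta: float = 0.5,
) -> tuple[list[AssignmentResult], list[int]]:
    """Resolve all queries of one frame transition.

    Each current-frame label is scored per query by the mean prediction
    over that label's pixels inside the query's crop; labels scoring
    >= ``theta`` are candidates.  Conflicts are resolved greedily in order
    of descending score, each query taking at most its top two candidates
    (two -> division, one -> continuation, none -> exited) and each label
    going to at most one query.  Returns the assignments plus the orphan
    labels nobody claimed (cells that entered the field).
    """
    results: dict[int, AssignmentResult] = {}
    triples = []
    for sample, pred in predictions:
        r0, r1, c0, c1 = sample.crop_box
        sub = curr_labels[r0:r1, c0:c1]
        pred = np.asarray(pred, dtype=np.float64)
        if pred.shape != sub.shape:
            raise ValueError("prediction shape does not match the crop box")
        scores: dict[int, float] = {}
        for lab in np.unique(sub):
            if lab == 0:
                continue
            scores[int(lab)] = float(pred[sub == lab].mean())
        results[sample.prev_label] = AssignmentResult(
            prev_label=sample.prev_label, scores=scores,
            outcome=("exited", None))
        ranked = sorted(scores.items(), key=lambda kv: -kv[1])[:2]
        for lab, sc in ranked:
            if sc >= theta:
                triples.append((sc, sample.prev_label, lab))
    triples.sort(key=lambda t: -t[0])
    taken: dict[int, int] = {}
    accepted: dict[int, list[int]] = {q: [] for q in results}
    for sc, q, lab in triples:
        if lab in taken or len(accepted[q]) >= 2:
            continue
        taken[lab] = q
        accepted[q].append(lab)
    for q, labs in accepted.items():
        if len(labs) == 2:
            results[q].outcome = ("divides", labs[0], labs[1])
        elif len(labs) == 1:
            results[q].outcome = ("continues", labs[0])
    orphans = [int(l) for l in np.unique(curr_labels)
               if l > 0 and int(l) not in taken]
    return list(results.values()), orphans


class OraclePredictor:
    """Bypasses the network: predicts the ground-truth target mask.

    ``tracking_gt`` is the per-transition assignment ground truth emitted by
    the simulator; transition index t maps frame t-1 queries to frame t.
    """

    def __init__(self, tracking_gt: list[dict]):
        self.tracking_gt = tracking_gt

    def __call__(self, sample: TrackingSample, transition: int,
                 curr_labels: np.ndarray) -> np.ndarray:
        outcome = self.tracking_gt[transition].get(sample.prev_label,
                                                   ("exited", None))
        r0, r1, c0, c1 = sample.crop_box
        sub = curr_labels[r0:r1, c0:c1]
        targets = [l for l in outcome[1:] if l is not None] \
            if outcome[0] != "exited" else []
        return np.isin(sub, targets).astype(np.float64)


class ModelPredictor:
    """Runs a trained tracking network on the stacked sample planes."""

    def __init__(self, model):
        self.model = model

    def __call__(self, sample: TrackingSample, transition: int,
                 curr_labels: np.ndarray) -> np.ndarray:
        return np.asarray(self.model.predict(sample.stacked()),
                          dtype=np.float64)


@dataclass
class CellRecord:
    cell_id: int
    first_frame: int
    mother_id: int | None = None
    last_frame: int = 0
    pole_history: str = ""
    poles_assigned: bool = False
    daughters: tuple[int, int] | None = None
    labels: dict[int, int] = field(default_factory=dict)     # frame -> label
    pole_old: dict[int, np.ndarray] = field(default_factory=dict)
    pole_new: dict[int, np.ndarray] = field(default_factory=dict)


@dataclass
class TrackResult:
    cells: dict[int, CellRecord]
    assignments: list[dict[int, tuple]]   # per transition: prev label -> outcome
    masks: LabelMask

    def lineage_table(self) -> pd.DataFrame:
        rows = []
        for rec in self.cells.values():
            rows.append({
                "cell_id": rec.cell_id,
                "mother_id": rec.mother_id if rec.mother_id is not None else -1,
                "first_frame": rec.first_frame,
                "last_frame": rec.last_frame,
                "pole_history": rec.pole_history,
                "daughter1": rec.daughters[0] if rec.daughters else -1,
                "daughter2": rec.daughters[1] if rec.daughters else -1,
            })
        return pd.DataFrame(rows).sort_values("cell_id").reset_index(drop=True)


def _endpoints_of(labels: np.ndarray, lab: int):
    return cell_endpoints(labels == lab)


def detect_division_and_poles(
    mother: CellRecord,
    t: int,
    lab1: int,
    lab2: int,
    curr_labels: np.ndarray,
    d1: CellRecord,
    d2: CellRecord,
) -> None:
    """Assign poles and O/N letters to the two daughters of a division.

    Septum = midpoint of the daughters' mutually nearest endpoints; each
    daughter's endpoint nearest the septum is its new pole.  If the mother's
    poles are known, the daughter whose far endpoint lies nearest the
    mother's old pole appends 'O' and its sibling 'N'; an age-unknown mother
    initialises pole tracking without letters.  Degenerate daughter geometry
    (no resolvable endpoints) leaves poles unknown and withholds letters.
    """
    e1 = _endpoints_of(curr_labels, lab1)
    e2 = _endpoints_of(curr_labels, lab2)
    if e1 is None or e2 is None:
        d1.pole_history = d2.pole_history = mother.pole_history
        d1.poles_assigned = d2.poles_assigned = False
        return
    pairs = [(np.linalg.norm(a - b), i, j)
             for i, a in enumerate(e1) for j, b in enumerate(e2)]
    _, i, j = min(pairs, key=lambda p: p[0])
    septum = (e1[i] + e2[j]) / 2.0
    new1, far1 = e1[i], e1[1 - i]
    new2, far2 = e2[j], e2[1 - j]

    d1.poles_assigned = d2.poles_assigned = True
    d1.pole_new[t], d1.pole_old[t] = new1, far1
    d2.pole_new[t], d2.pole_old[t] = new2, far2
    if mother.poles_assigned and (t - 1) in mother.pole_old:
        mo = mother.pole_old[t - 1]
        # daughter whose far endpoint sits nearest the mother's old pole
        if np.linalg.norm(far1 - mo) <= np.linalg.norm(far2 - mo):
            d1.pole_history = mother.pole_history + "O"
            d2.pole_history = mother.pole_history + "N"
        else:
            d1.pole_history = mother.pole_history + "N"
            d2.pole_history = mother.pole_history + "O"
    else:
        d1.pole_history = d2.pole_history = ""


def _update_continuation_poles(rec: CellRecord, t: int,
                               curr_labels: np.ndarray, lab: int) -> None:
    if not rec.poles_assigned:
        return
    ends = _endpoints_of(curr_labels, lab)
    if ends is None or (t - 1) not in rec.pole_old:
        return
    po, pn = rec.pole_old[t - 1], rec.pole_new[t - 1]
    a, b = ends
    # match endpoints to previous poles by total displacement
    if (np.linalg.norm(a - po) + np.linalg.norm(b - pn)
            <= np.linalg.norm(b - po) + np.linalg.norm(a - pn)):
        rec.pole_old[t], rec.pole_new[t] = a, b
    else:
        rec.pole_old[t], rec.pole_new[t] = b, a


def track_movie(
    masks: LabelMask,
    predictor,
    movie: Movie | None = None,
    crop: tuple[int, int] = (256, 256),
    theta: float = 0.5,
) -> TrackResult:
    """Track every cell across a movie's frames and reconstruct the lineage.

    ``predictor(sample, transition, curr_labels) -> probability plane`` is
    either a trained-network predictor or the ground-truth oracle.  Phase
    images are taken from ``movie`` when given (normalised per frame);
    without a movie, blank phase planes are used, which suits mask-only
    oracle runs.
    """
    n_frames = len(masks)
    phase = [normalize_frame(movie.phase(t)) if movie is not None
             else np.zeros_like(masks[t], dtype=np.float64)
             for t in range(n_frames)]

    cells: dict[int, CellRecord] = {}
    next_id = 0
    label_to_cell: dict[int, int] = {}
    for lab in masks.labels(0):
        rec = CellRecord(cell_id=next_id, first_frame=0, last_frame=0)
        rec.labels[0] = int(lab)
        cells[next_id] = rec
        label_to_cell[int(lab)] = next_id
        next_id += 1

    assignments: list[dict[int, tuple]] = []
    for t in range(1, n_frames):
        prev_labels, curr_labels = masks[t - 1], masks[t]
        preds = []
        for lab, cid in label_to_cell.items():
            sample = build_sample(phase[t - 1], prev_labels, phase[t],
                                  curr_labels, lab, crop)
            preds.append((sample, predictor(sample, t - 1, curr_labels)))
        results, orphans = score_and_assign(preds, curr_labels, theta)
        new_map: dict[int, int] = {}
        frame_events: dict[int, tuple] = {}
        for res in results:
            cid = label_to_cell[res.prev_label]
            rec = cells[cid]
            frame_events[res.prev_label] = res.outcome
            kind = res.outcome[0]
            if kind == "continues":
                lab = res.outcome[1]
                rec.labels[t] = lab
                rec.last_frame = t
                _update_continuation_poles(rec, t, curr_labels, lab)
                new_map[lab] = cid
            elif kind == "divides":
                lab1, lab2 = res.outcome[1], res.outcome[2]
                d1 = CellRecord(cell_id=next_id, first_frame=t, mother_id=cid)
                d2 = CellRecord(cell_id=next_id + 1, first_frame=t,
                                mother_id=cid)
                next_id += 2
                d1.labels[t] = lab1
                d2.labels[t] = lab2
                d1.last_frame = d2.last_frame = t
                detect_division_and_poles(rec, t, lab1, lab2, curr_labels,
                                          d1, d2)
                rec.daughters = (d1.cell_id, d2.cell_id)
                cells[d1.cell_id] = d1
                cells[d2.cell_id] = d2
                new_map[lab1] = d1.cell_id
                new_map[lab2] = d2.cell_id
        for lab in orphans:
            rec = CellRecord(cell_id=next_id, first_frame=t, last_frame=t)
            rec.labels[t] = lab
            cells[next_id] = rec
            new_map[lab] = next_id
            next_id += 1
        label_to_cell = new_map
        assignments.append(frame_events)
    return TrackResult(cells=cells, assignments=assignments, masks=masks)


def build_feature_table(
    result: TrackResult,
    movie: Movie | None = None,
    pixel_size_um: float = 1.0,
) -> pd.DataFrame:
    """Flat (cell, frame) feature table: label, centroid, area, length and
    per-channel mean fluorescence."""
    fluor_channels = [ch for ch in (movie.channels if movie else [])
                      if movie and ch != movie.phase_channel]
    rows = []
    for rec in sorted(result.cells.values(), key=lambda r: r.cell_id):
        for t, lab in sorted(rec.labels.items()):
            mask = result.masks[t] == lab
            area = int(mask.sum())
            cy, cx = ndimage.center_of_mass(mask)
            row = {
                "cell_id": rec.cell_id, "frame": t, "label": lab,
                "area_px": area, "centroid_row": cy, "centroid_col": cx,
                "length_um": (cell_length(mask, pixel_size_um)
                              if area >= 2 else np.nan),
                "pole_history": rec.pole_history,
            }
            po = rec.pole_old.get(t)
            pn = rec.pole_new.get(t)
            row["pole_old_row"] = po[0] if po is not None else np.nan
            row["pole_old_col"] = po[1] if po is not None else np.nan
            row["pole_new_row"] = pn[0] if pn is not None else np.nan
            row["pole_new_col"] = pn[1] if pn is not None else np.nan
            for ch in fluor_channels:
                row[f"fluor_{ch}"] = fluorescence(mask, movie.channel(ch, t))
            rows.append(row)
    return pd.DataFrame(rows)


def make_training_samples(
    movie: Movie,
    masks: LabelMask,
    tracking_gt: list[dict],
    crop: tuple[int, int] = (64, 64),
    params: WeightParams | None = None,
    rng: np.random.Generator | None = None,
):
    """Generator of (stacked 4-plane input, target, weight map) tracking
    training samples drawn from a movie with ground-truth assignments."""
    rng = rng or np.random.default_rng()
    params = params or WeightParams()
    phase = [normalize_frame(movie.phase(t)) for t in range(movie.n_frames)]
    events = [(t, lab, outcome)
              for t, frame_map in enumerate(tracking_gt)
              for lab, outcome in frame_map.items()
              if outcome[0] != "exited"]
    if not events:
        raise ValueError("tracking ground truth holds no usable events")
    while True:
        t, lab, outcome = events[rng.integers(len(events))]
        sample = build_sample(phase[t], masks[t], phase[t + 1], masks[t + 1],
                              lab, crop)
        r0, r1, c0, c1 = sample.crop_box
        sub = masks[t + 1][r0:r1, c0:c1]
        targets = [l for l in outcome[1:] if l is not None
                   and (sub == l).any()]
        if not targets:
            continue
        target, wm = make_track_target(targets, sub, params)
        yield sample.stacked(), target.astype(np.float64), wm
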