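import itertools

import numpy as np
import pytest

from microtrack.evaluate import (density_label, pixel_metrics, seg_errors,
                                 seg_report, shift_harness, track_errors)
from microtrack.io import LabelMask


def _frame(*cells, shape=(64, 64)):
    out = np.zeros(shape, dtype=np.int32)
    for lab, (r0, r1, c0, c1) in enumerate(cells, start=1):
        out[r0:r1, c0:c1] = lab
    return out


def brute_force_seg_errors(pred, gt, correct_frac=0.75, merge_frac=0.25):
    """Independent per-definition recount using nothing but pixel loops."""
    pred_ids = sorted(set(pred.ravel()) - {0},
                      key=lambda p: -int((pred == p).sum()))
    gt_ids = sorted(set(gt.ravel()) - {0})
    gt_size = {g: int((gt == g).sum()) for g in gt_ids}
    inter = {}
    for p, g in itertools.product(pred_ids, gt_ids):
        inter[(p, g)] = int(np.sum((pred == p) & (gt == g)))
    errors = 0
    claimed = set()
    touched = set()
    for p in pred_ids:
        overlaps = {g: inter[(p, g)] for g in gt_ids if inter[(p, g)] > 0}
        touched |= set(overlaps)
        if not overlaps:
            errors += 1
            continue
        merged = [g for g, c in overlaps.items()
                  if c >= merge_frac * gt_size[g]]
        if len(merged) >= 2:
            errors += 2
            continue
        best = max(overlaps, key=overlaps.get)
        if overlaps[best] > correct_frac * int((pred == p).sum()) \
                and best not in claimed:
            claimed.add(best)
        else:
            errors += 1
    errors += sum(1 for g in gt_ids if g not in touched)
    return errors


class TestSegErrors:
    def test_perfect_prediction(self):
        gt = _frame((5, 15, 5, 30), (25, 35, 5, 30))
        assert seg_errors(gt, gt) == (0, 2)

    def test_merge_counts_two_errors(self):
        gt = _frame((5, 15, 5, 30), (16, 26, 5, 30))
        pred = _frame((5, 26, 5, 30))  # the two cells fused into one
        assert seg_errors(pred, gt)[0] == 2

    def test_split_counts_one_error(self):
        gt = _frame((5, 15, 5, 40))
        pred = _frame((5, 15, 5, 20), (5, 15, 22, 40))
        assert seg_errors(pred, gt)[0] == 1

    def test_missed_cell_counts_one_error(self):
        gt = _frame((5, 15, 5, 30), (25, 35, 5, 30))
        pred = _frame((5, 15, 5, 30))
        assert seg_errors(pred, gt)[0] == 1

    def test_spurious_object_counts_one_error(self):
        gt = _frame((5, 15, 5, 30))
        pred = _frame((5, 15, 5, 30), (40, 50, 40, 60))
        assert seg_errors(pred, gt)[0] == 1

    def test_agrees_with_brute_force_on_random_frames(self):
        rng = np.random.default_rng(0)
        for trial in range(30):
            gt = np.zeros((48, 48), dtype=np.int32)
            pred = np.zeros((48, 48), dtype=np.int32)
            for lab in range(1, int(rng.integers(1, 7))):
                r, c = rng.integers(0, 36, 2)
                gt[r:r + rng.integers(4, 12), c:c + rng.integers(4, 12)] = lab
            for lab in range(1, int(rng.integers(1, 7))):
                r, c = rng.integers(0, 36, 2)
                pred[r:r + rng.integers(4, 12),
                     c:c + rng.integers(4, 12)] = lab
            assert seg_errors(pred, gt)[0] == \
                brute_force_seg_errors(pred, gt), f"trial {trial}"


class TestPixelMetrics:
    def test_agrees_with_direct_summation(self, rng):
        pred = (rng.random((32, 32)) > 0.5).astype(int)
        gt = (rng.random((32, 32)) > 0.5).astype(int)
        m = pixel_metrics(pred, gt)
        inter = sum(1 for p, g in zip(pred.ravel(), gt.ravel())
                    if p and g)
        union = sum(1 for p, g in zip(pred.ravel(), gt.ravel()) if p or g)
        assert abs(m["iou"] - inter / union) < 1e-10
        assert abs(m["dice"] - 2 * inter / (pred.sum() + gt.sum())) < 1e-10
        assert m["tp_tn"] + m["fp"] + m["fn"] == pytest.approx(1.0, abs=1e-12)

    def test_report_rates(self):
        gt = _frame((5, 15, 5, 30))
        rep = seg_report(LabelMask(frames=[gt, gt]), LabelMask(frames=[gt, gt]))
        assert rep.error_rate == 0.0
        assert rep.total_cells == 2


def _chain(events):
    """Helper: list of per-transition dicts."""
    return [dict(e) for e in events]


class TestTrackErrors:
    def test_identical_streams(self):
        gt = _chain([{1: ("continues", 1)}, {1: ("divides", 1, 2)},
                     {1: ("continues", 1), 2: ("continues", 2)}])
        assert track_errors(gt, gt) == (0, 4)

    def test_missed_in_field_cell(self):
        gt = _chain([{1: ("continues", 1)}])
        pred = _chain([{1: ("exited", None)}])
        assert track_errors(pred, gt)[0] == 1

    def test_wrong_continuation(self):
        gt = _chain([{1: ("continues", 1), 2: ("continues", 2)}])
        pred = _chain([{1: ("continues", 2), 2: ("continues", 1)}])
        assert track_errors(pred, gt)[0] == 2

    def test_division_two_frames_late_not_an_error(self):
        gt = _chain([
            {1: ("divides", 1, 2)},
            {1: ("continues", 1), 2: ("continues", 2)},
            {1: ("continues", 1), 2: ("continues", 2)},
        ])
        pred = _chain([
            {1: ("continues", 1)},          # still sees one cell
            {1: ("continues", 1)},
            {1: ("divides", 1, 2)},          # division detected 2 late
        ])
        errs, n = track_errors(pred, gt, tolerance=3)
        assert errs == 0
        assert n == 5

    def test_division_beyond_tolerance_is_error(self):
        gt = _chain([
            {1: ("divides", 1, 2)},
            {1: ("continues", 1), 2: ("continues", 2)},
            {1: ("continues", 1), 2: ("continues", 2)},
            {1: ("continues", 1), 2: ("continues", 2)},
            {1: ("continues", 1), 2: ("continues", 2)},
        ])
        pred = _chain([
            {1: ("continues", 1)},
            {1: ("continues", 1)},
            {1: ("continues", 1)},
            {1: ("continues", 1)},
            {1: ("divides", 1, 2)},          # 4 frames late
        ])
        assert track_errors(pred, gt, tolerance=3)[0] >= 1

    def test_false_division_is_error(self):
        gt = _chain([{1: ("continues", 1), 2: ("continues", 2)}])
        pred = _chain([{1: ("divides", 1, 2), 2: ("exited", None)}])
        assert track_errors(pred, gt)[0] >= 1


class TestShiftHarness:
    def test_row_count_and_unshifted_oracle(self, small_colony):
        _, masks, tracking, _ = small_colony
        distances = [2, 5, 10]
        df = shift_harness(masks, tracking, distances, n_events=10,
                           rng=np.random.default_rng(0))
        assert len(df) == 4 * len(distances) + 1
        unshifted = df[df["direction"] == "unshifted"]
        assert unshifted["mean_overlap_pct"].iloc[0] == pytest.approx(100.0)

    def test_fixed_crop_overlap_decays_monotonically(self, small_colony):
        _, masks, tracking, _ = small_colony
        distances = [1, 2, 5, 10, 20, 40]
        df = shift_harness(masks, tracking, distances,
                           predictor_sees_shift=False, n_events=15,
                           rng=np.random.default_rng(1))
        mean_by_d = df.groupby("distance")["mean_overlap_pct"].mean()
        vals = mean_by_d.sort_index().to_numpy()
        assert np.all(np.diff(vals) <= 1e-9)

    def test_density_labels(self):
        assert density_label(3) == "low"
        assert density_label(22) == "medium"
        assert density_label(300) == "high"
        assert density_label(60) == "intermediate"
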