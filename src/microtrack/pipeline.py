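"""Pipeline orchestration: segment -> track -> lineage/features.

Each stage writes its outputs under the configured output directory and is
resumable: a stage whose outputs already exist is skipped on rerun.  A run
manifest records the config hash, seeds and package versions.  Stage
failures abort with the stage name attached.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .io import (LabelMask, Movie, read_mask_sequence, read_movie,
                 write_mask_sequence, write_results)
from .track import (CellRecord, ModelPredictor, TrackResult,
                    build_feature_table, track_movie)
from .unet import UNet

log = logging.getLogger("microtrack")

__all__ = ["run_pipeline", "save_track_result", "load_track_result"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def save_track_result(result: TrackResult, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cells = []
    for rec in result.cells.values():
        cells.append({
            "cell_id": rec.cell_id, "mother_id": rec.mother_id,
            "first_frame": rec.first_frame, "last_frame": rec.last_frame,
            "pole_history": rec.pole_history,
            "poles_assigned": rec.poles_assigned,
            "daughters": list(rec.daughters) if rec.daughters else None,
            "labels": {str(t): int(l) for t, l in rec.labels.items()},
            "pole_old": {str(t): [float(v) for v in p]
                         for t, p in rec.pole_old.items()},
            "pole_new": {str(t): [float(v) for v in p]
                         for t, p in rec.pole_new.items()},
        })
    payload = {
        "cells": cells,
        "assignments": [
            {str(lab): list(outcome) for lab, outcome in frame_map.items()}
            for frame_map in result.assignments
        ],
    }
    path = out_dir / "tracking.json"
    path.write_text(json.dumps(payload))
    return path


def load_track_result(out_dir: str | Path, masks: LabelMask) -> TrackResult:
    payload = json.loads((Path(out_dir) / "tracking.json").read_text())
    cells: dict[int, CellRecord] = {}
    for c in payload["cells"]:
        rec = CellRecord(
            cell_id=c["cell_id"], first_frame=c["first_frame"],
            mother_id=c["mother_id"], last_frame=c["last_frame"],
            pole_history=c["pole_history"],
            poles_assigned=c["poles_assigned"],
            daughters=tuple(c["daughters"]) if c["daughters"] else None,
        )
        rec.labels = {int(t): l for t, l in c["labels"].items()}
        rec.pole_old = {int(t): np.array(p) for t, p in c["pole_old"].items()}
        rec.pole_new = {int(t): np.array(p) for t, p in c["pole_new"].items()}
        cells[rec.cell_id] = rec
    assignments = [
        {int(lab): tuple(outcome) for lab, outcome in frame_map.items()}
        for frame_map in payload["assignments"]
    ]
    return TrackResult(cells=cells, assignments=assignments, masks=masks)


def run_pipeline(config: PipelineConfig,
                 movie: Movie | None = None) -> dict[str, Path]:
    """Run segment -> track -> features on a movie, resumably.

    ``movie`` may be passed in memory; otherwise it is read from
    ``config.paths.movie``.  Returns the paths of the stage outputs.
    """
    out_dir = Path(config.paths.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir)
    outputs: dict[str, Path] = {}

    if movie is None:
        if config.paths.movie is None:
            raise ValueError("no movie given (config.paths.movie is unset)")
        movie = read_movie(config.paths.movie, config.channels,
                           phase_channel=config.phase_channel,
                           interval_min=config.interval_min,
                           pixel_size_um=config.pixel_size_um)

    # -- segment ------------------------------------------------------------
    masks_dir = out_dir / "masks"
    stage = "segment"
    try:
        if masks_dir.exists() and any(masks_dir.glob("*.tif")):
            log.info("segment: reusing masks in %s", masks_dir)
            masks = read_mask_sequence(masks_dir)
        else:
            if config.paths.seg_weights is None:
                raise ValueError("paths.seg_weights is required to segment")
            from .seg import segment_movie
            model = UNet.load(config.paths.seg_weights)
            log.info("segment: %d frames", movie.n_frames)
            masks = segment_movie(
                movie, model, lo_pct=config.normalize_lo_pct,
                hi_pct=config.normalize_hi_pct,
                threshold=config.seg_threshold, min_area=config.min_area_px,
                window=(config.tile_window, config.tile_window),
                overlap=config.tile_overlap)
            write_mask_sequence(masks, masks_dir)
        outputs["masks"] = masks_dir
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(stage, exc) from exc

    # -- track --------------------------------------------------------------
    stage = "track"
    try:
        if (out_dir / "tracking.json").exists():
            log.info("track: reusing tracking.json")
            result = load_track_result(out_dir, masks)
        else:
            if config.paths.track_weights is None:
                raise ValueError("paths.track_weights is required to track")
            predictor = ModelPredictor(UNet.load(config.paths.track_weights))
            log.info("track: %d transitions", len(masks) - 1)
            result = track_movie(
                masks, predictor, movie=movie,
                crop=(config.tracking_crop, config.tracking_crop),
                theta=config.theta_assign)
            save_track_result(result, out_dir)
        outputs["tracking"] = out_dir / "tracking.json"
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # -- features -----------------------------------------------------------
    stage = "features"
    try:
        features = build_feature_table(result, movie=movie,
                                       pixel_size_um=config.pixel_size_um
                                       or 1.0)
        lineage = result.lineage_table()
        paths = write_results(lineage, masks, features, out_dir)
        outputs.update(paths)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {s: config.derive_seed(s)
                        for s in ("segment", "track", "features")},
        "versions": {"microtrack": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    outputs["manifest"] = out_dir / "manifest.json"
    return outputs


def _setup_logging(out_dir: Path) -> None:
    if not any(isinstance(h, logging.FileHandler)
               and Path(h.baseFilename).parent == out_dir
               for h in log.handlers):
        handler = logging.FileHandler(out_dir / "run.log")
        handler.setFormatter(logging.Formatter(
            "%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)
    log.setLevel(logging.INFO)
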