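"""Single YAML configuration with strict validation and seed fan-out.

Every numeric default of the pipeline lives here exactly once; unknown keys
are rejected.  A single global ``seed`` fans out deterministically into
per-stage seeds so each stage is reproducible on its own.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

__all__ = ["PipelineConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelSpecConfig(_Strict):
    depth: int = 4
    base_filters: int = 64


class TrainStageConfig(_Strict):
    epochs: int = 600
    steps_per_epoch: int = 300
    batch_size: int = 1
    learning_rate: float = 1e-4


class WeightsConfig(_Strict):
    w_skeleton: float = 4.0
    w_border_skeleton: float = 8.0
    w_interface: float = 0.25
    w_background_base: float = 0.1
    d_border_px: float = 2.0
    track_decay_px: float = 32.0


class AugmentationConfig(_Strict):
    sigma_blur: float = 1.0
    sigma_noise: float = 0.03
    max_track_shift: int = 5
    max_shift: int = 30
    scale_min: float = 0.9
    scale_max: float = 1.1
    rotation_deg: float = 180.0
    flip: bool = True
    gamma_min: float = 0.7
    gamma_max: float = 1.3


class TrainingConfig(_Strict):
    segmentation: TrainStageConfig = TrainStageConfig()
    tracking: TrainStageConfig = TrainStageConfig(
        epochs=500, batch_size=2, learning_rate=1e-5)
    weights: WeightsConfig = WeightsConfig()
    augmentation: AugmentationConfig = AugmentationConfig()
    variable_background: bool = True


class PathsConfig(_Strict):
    movie: str | None = None
    masks: str | None = None
    seg_weights: str | None = None
    track_weights: str | None = None
    out_dir: str = "microtrack_out"


class PipelineConfig(_Strict):
    """Everything the simulate/train/segment/track/features/evaluate stages
    need, with one default per parameter."""

    paths: PathsConfig = PathsConfig()
    channels: dict[str, str] = {"phase": ""}
    phase_channel: str = "phase"
    interval_min: float = 5.0
    pixel_size_um: float = 0.129
    seed: int = 0
    model_segmentation: ModelSpecConfig = ModelSpecConfig()
    model_tracking: ModelSpecConfig = ModelSpecConfig()
    training: TrainingConfig = TrainingConfig()
    # inference
    tracking_crop: int = 256
    seg_threshold: float = 0.5
    min_area_px: int = 20
    tile_window: int = 512
    tile_overlap: int = 128
    theta_assign: float = 0.5
    normalize_lo_pct: float = 0.1
    normalize_hi_pct: float = 99.9
    # evaluation
    division_tolerance_frames: int = 3
    # growth statistics
    min_frames_growth: int = 3
    first_frame_cutoff: int | None = None

    _STAGES = ("simulate", "train-seg", "train-track", "segment", "track",
               "features", "evaluate")

    def derive_seed(self, stage: str) -> int:
        """Per-stage seed derived deterministically from the global seed."""
        if stage not in self._STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        return int(np.random.SeedSequence(
            [self.seed, self._STAGES.index(stage)]).generate_state(1)[0]
            % (2**31))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        return cls.model_validate(data)


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    return PipelineConfig.from_yaml(Path(path).read_text())
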