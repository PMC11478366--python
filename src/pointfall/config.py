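"""Run configuration: every knob of the study pipeline, YAML-serializable.

A run is reproducible from ``(RunConfig, seed)``; the config is plain data so
it can be hashed for stage caching by the pipeline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .core import ParameterError

__all__ = ["TrainingConfig", "ModelDims", "FallWindows", "RunConfig"]

#: Split ratios reported by the study protocol (train fraction).
STUDY_RATIOS = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass
class TrainingConfig:
    """Optimizer schedule for the recurrent classifiers.

    Ten epochs at a flat learning rate of 0.001 with per-epoch reshuffling;
    mini-batches of 128 give per-epoch iteration counts matching the study's
    reported 51–93 range across split ratios.
    """

    epochs: int = 10
    learning_rate: float = 1e-3
    batch_size: int = 128
    shuffle_each_epoch: bool = True
    optimizer: str = "adam"  # or "sgd"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ParameterError("learning rate must be positive")


@dataclass
class ModelDims:
    """Hidden sizes of the stacked recurrent networks (never dictated by the
    sensor; these are package defaults of the right order of magnitude)."""

    fc1_dim: int = 32
    hidden: int = 100  # the recurrent "inner size" LS
    projection: int = 32  # projected-LSTM bottleneck p < LS


@dataclass
class FallWindows:
    """Frame-window conventions for peri-fall and post-fall analysis.

    The peri-fall window spans 40 frames (4 s at 10 Hz), 20 on each side of
    the detected fall instant.  Post-fall speed is averaged over frames
    t*+10 … t*+50 inclusive.
    """

    peri_half: int = 20
    post_lo: int = 10
    post_hi: int = 50
    dz_threshold: float = -0.15  # m per frame-step; below this a fall is declared
    speed_smooth_window: int = 3


@dataclass
class RunConfig:
    seed: int = 42
    frame_rate: float = 10.0
    n_fall_tracks: int = 12
    n_sit_tracks: int = 14
    windows: FallWindows = field(default_factory=FallWindows)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    dims: ModelDims = field(default_factory=ModelDims)
    window_length: int = 20  # frames per classifier input sequence (2 s)
    window_stride: int = 1
    confidence: float = 0.95  # ellipsoid coverage probability
    split_ratios: tuple[float, ...] = STUDY_RATIOS
    leave_one_out: bool = True
    quant_formats: tuple[str, ...] = ("8(4.4)", "16(8.8)", "32(16.16)")
    out_dir: str = "results"

    # -- serialization ---------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["split_ratios"] = list(self.split_ratios)
        d["quant_formats"] = list(self.quant_formats)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "windows" in d and isinstance(d["windows"], dict):
            d["windows"] = FallWindows(**d["windows"])
        if "training" in d and isinstance(d["training"], dict):
            d["training"] = TrainingConfig(**d["training"])
        if "dims" in d and isinstance(d["dims"], dict):
            d["dims"] = ModelDims(**d["dims"])
        if "split_ratios" in d:
            d["split_ratios"] = tuple(d["split_ratios"])
        if "quant_formats" in d:
            d["quant_formats"] = tuple(d["quant_formats"])
        return cls(**d)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
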