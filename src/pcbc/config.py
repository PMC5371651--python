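"""Pipeline configuration with task presets and lossless YAML round-trip."""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclasses.dataclass
class PipelineConfig:
    """Every knob of the pipeline in one flat, serialisable record.

    Defaults mirror the published task settings where one exists: 50
    update iterations, 0.001 response floor, 2-pixel stage-2 smoothing;
    per-task presets carry the clustering threshold kappa (0.85 digits,
    0.9 faces, 0.4 cars), the minimum cluster size lambda (0 or 12) and
    the preprocessing sigma (4, 2.5*sqrt(delta) or 3.5 pixels).
    """

    task: str = "classify"               # "classify" | "detect"
    sigma: float = 3.0
    kappa: float = 0.85
    lambda_min: int = 0
    patch_size: int = 15
    scales: tuple = (1.0,)
    smoothing_sigma: float = 2.0
    scale_sigma: float = 0.0             # 0 disables scale smoothing
    n_iter: int = 50
    response_floor: float = 1e-3
    score_threshold: float = 0.0
    nms: bool = True
    seed: int = 0
    # synthetic-data knobs
    n_classes: int = 10
    image_size: int = 28
    n_train: int = 500
    n_test: int = 200
    n_scenes: int = 20
    n_negative: int = 10
    crop_size: int = 21
    n_crops: int = 30
    jitter_px: float = 2.0
    jitter_deg: float = 8.0
    glyph_scale_range: tuple = (0.9, 1.1)
    noise_sigma: float = 0.03
    illum_max: float = 0.25
    clutter: float = 0.08
    scene_size: int = 64
    max_objects: int = 3

    def __post_init__(self):
        if self.task not in ("classify", "detect"):
            raise ValueError(f"unknown task {self.task!r}")
        self.scales = tuple(float(s) for s in self.scales)
        self.glyph_scale_range = tuple(float(s)
                                       for s in self.glyph_scale_range)

    # --- presets -----------------------------------------------------
    @classmethod
    def digits(cls) -> "PipelineConfig":
        """Fixed-location digit-style categorisation preset."""
        return cls(task="classify", sigma=4.0, kappa=0.85, lambda_min=0)

    @classmethod
    def faces(cls, delta: float = 1.0) -> "PipelineConfig":
        """Identification preset; sigma follows the 2.5*sqrt(delta) rule."""
        return cls(task="classify", sigma=2.5 * math.sqrt(delta), kappa=0.9,
                   lambda_min=0)

    @classmethod
    def cars(cls) -> "PipelineConfig":
        """Localisation preset."""
        return cls(task="detect", sigma=3.5, kappa=0.4, lambda_min=12,
                   patch_size=15)

    # --- serialisation -----------------------------------------------
    def to_yaml(self, path=None) -> str:
        data = dataclasses.asdict(self)
        data["scales"] = list(self.scales)
        data["glyph_scale_range"] = list(self.glyph_scale_range)
        text = yaml.safe_dump(data, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        """Load from a YAML string or file path."""
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**data)
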