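"""Pipeline configuration with study defaults, YAML-serializable.

Defaults marked "protocol" reproduce the acquisition protocol's stated
settings (10 Hz kinematic and 50 Hz kinetic cutoffs, 0.1 s registration
delay, 101 %-stance points, 95 % CI); the rest are package design choices
documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ValidationError

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    marker_cutoff_hz: float = 10.0  # protocol
    kinetic_cutoff_hz: float = 50.0  # protocol (clipped below Nyquist at run time)
    registration_delay_s: float = 0.1  # protocol
    resample_points: int = 101  # protocol (% stance grid)
    ci_level: float = 0.95  # protocol
    stance_floor_n: float = 10.0
    stance_bw_fraction: float = 0.015
    stance_min_frames: int = 3
    min_stance_s: float = 0.2
    segmentation_axis: str = "foot"  # "foot" (C1->H2) or "global_y"
    joint_center_pairs: dict = field(default_factory=dict)  # overrides per joint
    frame_recipes: dict = field(default_factory=dict)  # overrides per segment
    marker_map: dict = field(default_factory=dict)  # lab label -> canonical label

    def __post_init__(self) -> None:
        if self.resample_points < 2:
            raise ValidationError("resample_points must be >= 2")
        if not 0 < self.ci_level < 1:
            raise ValidationError("ci_level must be in (0, 1)")
        if self.segmentation_axis not in ("foot", "global_y"):
            raise ValidationError("segmentation_axis must be 'foot' or 'global_y'")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["frame_recipes"] = {k: repr(v) for k, v in self.frame_recipes.items()}
        return d


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    data.pop("frame_recipes", None)  # recipes are Python-level overrides only
    return PipelineConfig(**data)


def save_config(cfg: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    return path
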