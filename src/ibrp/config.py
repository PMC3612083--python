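"""Pipeline configuration.

The default configuration is the standard bead-masking recipe:
Gaussian radius 1 px, rolling-ball radius 400 px, particle size
200-infinity px^2, circularity 0.60-1.00, edge particles excluded,
watershed on.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .segmentation import SegmentationParams

__all__ = ["PipelineConfig", "DEFAULT_PROFILE"]


@dataclass(frozen=True)
class PipelineConfig:
    gaussian_radius_px: float = 1.0
    ball_radius_px: float = 400.0
    threshold_method: str = "otsu"
    threshold_value: float | None = None
    min_area_px: int = 200
    circularity_min: float = 0.60
    circularity_max: float = 1.00
    exclude_edges: bool = True
    watershed: bool = True
    blank_autofluorescence: float = 0.0
    saturation_policy: str = "exclude"
    snr_dilation_px: int = 3

    def segmentation_params(self) -> SegmentationParams:
        return SegmentationParams(
            threshold_method=self.threshold_method,
            threshold_value=self.threshold_value,
            min_area_px=self.min_area_px,
            circ_min=self.circularity_min,
            circ_max=self.circularity_max,
            exclude_edges=self.exclude_edges,
            watershed_enabled=self.watershed,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path

    def digest(self) -> str:
        """Stable hash of the configuration, for run logs."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


#: The default analysis recipe, spelled out for one-command reproduction.
DEFAULT_PROFILE = PipelineConfig()
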