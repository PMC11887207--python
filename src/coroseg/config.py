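"""Pipeline configuration.

Defaults are the published operating point of the method: patches are 32x32
pixels at the 0.25 mm isotropic working resolution, intensities are clipped to
the aorta-derived [100, 600] HU band before clustering, Ward's algorithm runs
with 7 clusters, the vessel-path search stops below 100 HU, the fallback
threshold is 150 HU, reconstruction uses a 2 mm sphere (perpendicular variant)
or a 4 mm per-plane brush (3-axis variant), and the final mask is median
smoothed with a 1 mm kernel.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

from .errors import ParameterError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    n_clusters: int = 7
    hu_low: float = 100.0
    hu_high: float = 600.0
    stop_hu: float = 100.0
    fallback_hu: float = 150.0
    sphere_radius_mm: float = 2.0
    brush_radius_mm: float = 4.0
    smooth_mm: float = 1.0
    resample_mm: float = 0.25
    centerline_step_mm: float = 0.25
    patch_size: int = 32
    forward_only_mm: float = 2.0  # half-space clipping extent after a bifurcation
    method: str = "perp"  # "perp" | "3axis"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hu_low >= self.hu_high:
            raise ParameterError(
                f"hu_low must be < hu_high, got ({self.hu_low}, {self.hu_high})")
        if not 1 <= self.n_clusters <= self.patch_size ** 2:
            raise ParameterError(f"n_clusters out of range: {self.n_clusters}")
        for name in ("sphere_radius_mm", "brush_radius_mm", "smooth_mm",
                     "resample_mm", "centerline_step_mm"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.method not in ("perp", "3axis"):
            raise ParameterError(f"method must be 'perp' or '3axis', got {self.method}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))
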