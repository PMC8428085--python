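"""Run configuration: every analysis constant, surfaced and serializable.

Defaults mirror the reference acquisition conditions (140 px/mm, 20 s
capture interval, 5-frame bursts, 0.003 mm^2 dot-pixel filter) and the
detector settings documented in the methods note.  ``rt`` (the reaction
threshold for line segmentation) is experimentally determined per
cartridge lot and therefore has no universal default; pipelines that
need it fail loudly when it is missing.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    resolution_px_per_mm: float = 140.0
    capture_interval_s: float = 20.0
    burst_size: int = 5
    rt: float | None = None                  # reaction threshold, ADU
    min_area_mm2: float = 0.003
    histogram_smoothing_window: int = 5
    adaptive_window: int = 15                # line-defect neighborhood, px
    adaptive_t_percent: float = 20.0
    skew_window: int = 61                    # skew-check neighborhood, px
    skew_t_percent: float = 20.0
    skew_area_fraction: float = 0.05
    stall_tolerance_px: int = 2
    persistence_frames: int = 3
    stability_band: float = 0.5              # VR per minute, assay-specific
    stability_fraction: float = 0.95
    flow_axis: str = "horizontal"
    reverse_flow: bool = False
    expected_line_centers: tuple[float, float] | None = None  # full-frame px
    membrane_end_col: int | None = None      # full-frame px

    def __post_init__(self) -> None:
        if self.resolution_px_per_mm <= 0 or self.capture_interval_s <= 0:
            raise ValueError("resolution and capture interval must be positive")
        if self.burst_size < 1:
            raise ValueError("burst_size must be >= 1")
        if self.min_area_mm2 <= 0 or self.skew_area_fraction <= 0:
            raise ValueError("area thresholds must be positive")
        if not (0 < self.stability_fraction <= 1):
            raise ValueError("stability_fraction must be in (0, 1]")
        if self.stability_band <= 0:
            raise ValueError("stability_band must be positive")
        if self.flow_axis not in ("horizontal", "vertical"):
            raise ValueError("flow_axis must be horizontal or vertical")

    @property
    def vertical_axis(self) -> bool:
        return self.flow_axis == "vertical"

    def require_rt(self) -> float:
        if self.rt is None:
            raise ValueError("config field 'rt' (reaction threshold) is "
                             "required for line segmentation")
        return self.rt

    def with_overrides(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs) if kwargs else self

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["expected_line_centers"] is not None:
            d["expected_line_centers"] = list(d["expected_line_centers"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("expected_line_centers") is not None:
            d["expected_line_centers"] = tuple(d["expected_line_centers"])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
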