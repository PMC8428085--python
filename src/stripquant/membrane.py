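"""NC-membrane extraction from the final flow map.

Once the sample front has reached the end of the membrane ("flow
reached"), the wetted region coincides with the visible membrane, so
the tight bounding box of the final binary flow map locates the
membrane on the full frame.  That box is frozen and applied to every
subsequent frame to extract the membrane sub-image NCM(t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flow import label_components
from .io import AveragedFrame

__all__ = ["MembraneROI", "membrane_roi", "crop"]


@dataclass(frozen=True)
class MembraneROI:
    """Half-open row/col intervals of the membrane on the full frame."""

    row0: int
    row1: int
    col0: int
    col1: int

    def __post_init__(self) -> None:
        if not (self.row0 < self.row1 and self.col0 < self.col1):
            raise ValueError("degenerate ROI")

    @property
    def shape(self) -> tuple[int, int]:
        return self.row1 - self.row0, self.col1 - self.col0

    def to_dict(self) -> dict[str, int]:
        return {"row0": self.row0, "row1": self.row1,
                "col0": self.col0, "col1": self.col1}


def membrane_roi(final_flow_map: np.ndarray,
                 resolution_px_per_mm: float = 140.0) -> MembraneROI:
    """Tight bounding box of the largest component of the flow map."""
    comps = label_components(final_flow_map,
                             resolution_px_per_mm=resolution_px_per_mm)
    comp = comps.largest()
    if comp is None:
        raise ValueError("empty flow map: no membrane to segment")
    r0, r1, c0, c1 = comp.bbox
    return MembraneROI(row0=r0, row1=r1, col0=c0, col1=c1)


def crop(frame: AveragedFrame | np.ndarray, roi: MembraneROI) -> np.ndarray:
    """Exact sub-raster copy of the ROI."""
    px = frame.pixels if isinstance(frame, AveragedFrame) else np.asarray(frame)
    h, w = px.shape
    if roi.row0 < 0 or roi.col0 < 0 or roi.row1 > h or roi.col1 > w:
        raise ValueError(f"ROI {roi} out of bounds for frame {px.shape}")
    return px[roi.row0:roi.row1, roi.col0:roi.col1].copy()
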