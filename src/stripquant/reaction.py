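"""Test/control line quantification and reaction-stability detection.

Inside the extracted membrane NCM(t), pixels above an experimentally
determined reaction threshold RT form the binary line map B(t); after
8-connectivity labeling and the dot-pixel area filter, the surviving
components are the test line (upstream) and control line (downstream).
The segmented image SI(t) = NCM(t) * AFB(t) yields

- AT, AC : test/control pixel counts (areas),
- VT, VC : summed pixel intensities (volumes),
- AR = AT/AC,  VR = VT/VC,

with AR = VR = 0 while the sample is still flowing (no line detected).
The reaction stability time is the earliest capture time from which the
per-interval VR slope of at least a required fraction of samples
(default 95%) stays inside a band (assay-specific half-width).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .flow import DEFAULT_MIN_AREA_MM2, Component, label_components

__all__ = [
    "LineSegmentation", "RegionMeasurement", "ReactionSeries",
    "StabilityResult", "segment_lines", "measure_regions",
    "vr_slopes", "stability_time",
]


@dataclass(frozen=True)
class LineSegmentation:
    """Binary map, area-filtered map and per-line components.

    ``components`` holds every component surviving the area filter,
    sorted by centroid along the flow axis (upstream first); ``test``
    and ``control`` are the first two of these, when present.  More
    than two components is not an error here — the QC stage interprets
    extras as membrane irregularities.
    """

    membrane: np.ndarray             # NCM(t), the cropped raster
    binary_map: np.ndarray           # B(t)
    filtered_map: np.ndarray         # AFB(t)
    segmented_image: np.ndarray      # SI(t) = NCM(t) * AFB(t)
    labels: np.ndarray
    components: tuple[Component, ...]

    @property
    def test(self) -> Component | None:
        return self.components[0] if len(self.components) >= 1 else None

    @property
    def control(self) -> Component | None:
        return self.components[1] if len(self.components) >= 2 else None

    def component_mask(self, component: Component) -> np.ndarray:
        return self.labels == component.label


def segment_lines(membrane: np.ndarray, rt: float,
                  min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
                  resolution_px_per_mm: float = 140.0,
                  vertical_axis: bool = False,
                  reverse_flow: bool = False) -> LineSegmentation:
    """Threshold the membrane at RT and label the line components.

    The retained components are ordered along the flow direction; the
    upstream one is the test line (``reverse_flow`` flips the order for
    cartridges imaged with the sample pad on the far side).
    """
    membrane = np.asarray(membrane, dtype=np.float64)
    binary = membrane > rt
    comps = label_components(binary, min_area_mm2, resolution_px_per_mm)
    axis = 0 if vertical_axis else 1
    ordered = tuple(sorted(comps.components,
                           key=lambda c: c.centroid[axis],
                           reverse=reverse_flow))
    filtered = comps.foreground
    return LineSegmentation(membrane=membrane, binary_map=binary,
                            filtered_map=filtered,
                            segmented_image=membrane * filtered,
                            labels=comps.labels, components=ordered)


@dataclass(frozen=True)
class RegionMeasurement:
    """AT/AC/VT/VC and the AR/VR ratios at one time point."""

    t: float
    at: int
    ac: int
    vt: float
    vc: float
    ar: float
    vr: float


def measure_regions(seg: LineSegmentation, t: float = 0.0) -> RegionMeasurement:
    """Areas, volumes and ratios of the test/control components.

    Ratios are zero whenever the control denominator is zero — during
    sample flow no lines are detected, and AR/VR are defined as zero.
    """
    def _area_volume(comp: Component | None) -> tuple[int, float]:
        if comp is None:
            return 0, 0.0
        mask = seg.component_mask(comp)
        return comp.area_px, float(seg.segmented_image[mask].sum())

    at, vt = _area_volume(seg.test)
    ac, vc = _area_volume(seg.control)
    ar = at / ac if ac > 0 else 0.0
    vr = vt / vc if vc > 0 else 0.0
    return RegionMeasurement(t=t, at=at, ac=ac, vt=vt, vc=vc, ar=ar, vr=vr)


@dataclass
class ReactionSeries:
    """Ordered per-timepoint region measurements for one sample."""

    measurements: list[RegionMeasurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = self.t
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def t(self) -> np.ndarray:
        return np.array([m.t for m in self.measurements], dtype=np.float64)

    @property
    def vr(self) -> np.ndarray:
        return np.array([m.vr for m in self.measurements], dtype=np.float64)

    @classmethod
    def from_values(cls, t_s: Sequence[float],
                    vr: Sequence[float]) -> "ReactionSeries":
        """Build a VR-only series (areas/volumes left at zero)."""
        ms = [RegionMeasurement(t=float(t), at=0, ac=0, vt=0.0, vc=0.0,
                                ar=0.0, vr=float(v))
              for t, v in zip(t_s, vr, strict=True)]
        return cls(measurements=ms)


def vr_slopes(series: ReactionSeries) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval VR slope in VR units per *minute*.

    Returns ``(t_s, slope_per_min)`` where ``t_s`` are the timestamps of
    the later point of each interval.
    """
    t = series.t
    if t.size < 2:
        raise ValueError("need at least two points for slopes")
    dt_min = np.diff(t) / 60.0
    if np.any(dt_min <= 0):
        raise ValueError("timestamps must be strictly increasing")
    return t[1:], np.diff(series.vr) / dt_min


@dataclass(frozen=True)
class StabilityResult:
    """Reaction stability time over a set of samples."""

    stability_time_min: float | None
    band_halfwidth: float            # slope units, VR per minute
    fraction_required: float
    slope_times_s: np.ndarray
    in_band_fraction: np.ndarray     # fraction of samples in band per time
    slopes_at_stability: np.ndarray | None


def stability_time(series_list: Sequence[ReactionSeries],
                   band_halfwidth: float,
                   fraction_required: float = 0.95) -> StabilityResult:
    """Earliest capture time from which the in-band fraction persists.

    At the stability time t*, the fraction of samples whose VR slope
    magnitude is within ``band_halfwidth`` reaches at least
    ``fraction_required`` and remains so at every later captured time
    (persistence prevents a transient dip into the band from counting).
    Returns ``stability_time_min = None`` if never satisfied.  All
    series must share a common capture grid.
    """
    if not series_list:
        raise ValueError("need at least one reaction series")
    if not (0 < fraction_required <= 1):
        raise ValueError("fraction_required must be in (0, 1]")
    t0 = series_list[0].t
    slopes = []
    for s in series_list:
        ts, sl = vr_slopes(s)
        if not np.array_equal(s.t, t0):
            raise ValueError("series are not on a common capture grid")
        slopes.append(sl)
    slope_mat = np.vstack(slopes)                  # (n_samples, n_intervals)
    slope_times = t0[1:]
    frac = (np.abs(slope_mat) <= band_halfwidth).mean(axis=0)

    ok = frac >= fraction_required
    persistent = np.logical_and.accumulate(ok[::-1])[::-1]
    idx = np.flatnonzero(persistent)
    if idx.size == 0:
        return StabilityResult(None, band_halfwidth, fraction_required,
                               slope_times, frac, None)
    k = int(idx[0])
    return StabilityResult(float(slope_times[k] / 60.0), band_halfwidth,
                           fraction_required, slope_times, frac,
                           slope_mat[:, k].copy())
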