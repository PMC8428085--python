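"""Synthetic LFIA strip image stacks with known ground truth.

Emulates a fluorescence strip reader watching a lateral-flow cartridge:
a bright wetted region advances along the nitrocellulose (NC) membrane
with linearly decaying front speed, test/control lines develop with
saturating kinetics once the front has passed them, and every frame
carries Poisson shot noise.  Defects (skewed or stalled flow, stray
bright spots, bright/dark patches inside a line) can be injected with
known footprints so that the QC detectors can be validated without
hardware.

All intensities are in ADU on a 12-bit scale (clipped to [0, 4095]).
The canonical rendering frame is horizontal flow (left to right); a
vertical flow axis is produced by transposing the rendered image.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .io import ADC_MAX, FrameStack

__all__ = [
    "FlowAxis",
    "DefectKind",
    "StripGeometry",
    "KineticsParams",
    "DefectSpec",
    "GroundTruth",
    "default_defect",
    "generate_stack",
    "ground_truth",
]


class FlowAxis(str, enum.Enum):
    HORIZONTAL = "horizontal"
    VERTICAL = "vertical"


class DefectKind(str, enum.Enum):
    SKEWED_FLOW = "skewed_flow"
    STALLED_FLOW = "stalled_flow"
    MEMBRANE_BRIGHT_SPOT = "membrane_bright_spot"
    LINE_BRIGHT_PATCH = "line_bright_patch"
    LINE_DARK_PATCH = "line_dark_patch"


@dataclass(frozen=True)
class StripGeometry:
    """Pixel layout of the cartridge as seen by the camera.

    ``membrane_rows``/``membrane_cols`` are half-open pixel intervals of
    the NC membrane in the canonical (horizontal-flow) orientation; flow
    enters at ``membrane_cols[0]`` and the sink pad starts at
    ``membrane_cols[1]``.  Line centers are column coordinates along the
    flow axis; the test line sits upstream of the control line.
    """

    image_height_px: int = 160
    image_width_px: int = 480
    membrane_rows: tuple[int, int] = (40, 120)
    membrane_cols: tuple[int, int] = (40, 440)
    flow_axis: FlowAxis = FlowAxis.HORIZONTAL
    resolution_px_per_mm: float = 140.0
    test_line_center: int = 240
    control_line_center: int = 320
    line_width_px: int = 24

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.resolution_px_per_mm <= 0:
            raise ValueError("resolution_px_per_mm must be positive")
        r0, r1 = self.membrane_rows
        c0, c1 = self.membrane_cols
        if not (0 <= r0 < r1 <= self.image_height_px):
            raise ValueError("membrane_rows outside the image")
        if not (0 <= c0 < c1 <= self.image_width_px):
            raise ValueError("membrane_cols outside the image")
        for center in (self.test_line_center, self.control_line_center):
            if not (c0 <= center < c1):
                raise ValueError("line center outside the membrane interval")
        if self.test_line_center >= self.control_line_center:
            raise ValueError("test line must be upstream of the control line")
        if self.line_width_px <= 0:
            raise ValueError("line_width_px must be positive")

    @property
    def membrane_length_px(self) -> int:
        return self.membrane_cols[1] - self.membrane_cols[0]

    @property
    def membrane_width_px(self) -> int:
        return self.membrane_rows[1] - self.membrane_rows[0]


@dataclass(frozen=True)
class KineticsParams:
    """Flow-front and line-development kinetics.

    The front advances as l(t) = v0*t - (a/2)*t^2 (non-decreasing up to
    t = v0/a, clamped thereafter), consistent with a linearly decaying
    capillary flow speed.  Each line's integrated intensity grows as
    sat * (1 - exp(-(t - t_arrive)/tau)) after the front passes its
    center.
    """

    v0: float = 6.8                      # initial front speed, px/s
    a: float = 6.8 / 120.0               # linear deceleration, px/s^2
    line_saturation_level_t: float = 1500.0  # peak added intensity, ADU
    line_saturation_level_c: float = 1200.0
    tau_t: float = 180.0                 # saturating-growth time constant, s
    tau_c: float = 240.0
    background_level: float = 100.0      # dry strip, ADU
    flow_level: float = 1600.0           # wetted membrane, ADU

    def __post_init__(self) -> None:
        if self.v0 < 0:
            raise ValueError("v0 must be non-negative")
        if self.a < 0:
            raise ValueError("deceleration a must be non-negative")
        if self.line_saturation_level_t < 0 or self.line_saturation_level_c < 0:
            raise ValueError("saturation levels must be non-negative")
        if self.tau_t <= 0 or self.tau_c <= 0:
            raise ValueError("time constants must be positive")
        if self.background_level < 0 or self.flow_level < self.background_level:
            raise ValueError("need flow_level >= background_level >= 0")

    def front_position(self, t: float) -> float:
        """Unclamped-by-geometry front travel (px) at time t (s)."""
        if t < 0:
            raise ValueError("t must be non-negative")
        if self.a > 0:
            t = min(t, self.v0 / self.a)
        return self.v0 * t - 0.5 * self.a * t * t

    @property
    def max_travel_px(self) -> float:
        """Front travel at stall of the free kinetics: v0^2 / (2a)."""
        if self.a == 0:
            return math.inf
        return self.v0 * self.v0 / (2.0 * self.a)

    def arrival_time(self, distance_px: float) -> float | None:
        """First t with l(t) = distance, or None if never reached."""
        if distance_px <= 0:
            return 0.0
        if self.v0 == 0 or distance_px > self.max_travel_px:
            return None
        if self.a == 0:
            return distance_px / self.v0
        disc = self.v0 * self.v0 - 2.0 * self.a * distance_px
        disc = max(disc, 0.0)
        return (self.v0 - math.sqrt(disc)) / self.a


@dataclass(frozen=True)
class DefectSpec:
    """An injectable cartridge irregularity.

    Parameter semantics by kind (canonical horizontal orientation):

    - ``skewed_flow``: ``size_px`` = front lag (px) at the far membrane
      edge; each row's front clamps at membrane_end - lag(row), leaving
      a persistent dry wedge of area size_px * membrane_width / 2.
    - ``stalled_flow``: ``location`` = (row, col); the front never
      advances past column ``col`` (an obstruction).
    - ``membrane_bright_spot``: square bright blob, ``location`` =
      (row, col) center, side ``size_px``, added ``magnitude_adu``.
    - ``line_bright_patch`` / ``line_dark_patch``: square patch inside a
      line, ``location`` = (row, col) center, side ``size_px``,
      intensity shifted by +/- ``magnitude_adu``.
    """

    kind: DefectKind
    location: tuple[int, int] | None = None
    size_px: int = 0
    magnitude_adu: float = 0.0
    onset_time_s: float = 0.0

    def __post_init__(self) -> None:
        if self.magnitude_adu > ADC_MAX:
            raise ValueError("magnitude_adu exceeds the 12-bit ceiling")
        if self.onset_time_s < 0:
            raise ValueError("onset_time_s must be non-negative")


def default_defect(kind: DefectKind | str, geometry: StripGeometry) -> DefectSpec:
    """A defect of the given kind at its documented default magnitude."""
    kind = DefectKind(kind)
    r0, r1 = geometry.membrane_rows
    c0, c1 = geometry.membrane_cols
    mid_row = (r0 + r1) // 2
    if kind is DefectKind.SKEWED_FLOW:
        # dry wedge = lag * width / 2 = 10% of the membrane area
        lag = int(round(0.2 * geometry.membrane_length_px))
        return DefectSpec(kind, size_px=lag)
    if kind is DefectKind.STALLED_FLOW:
        stall_col = c0 + int(round(0.6 * geometry.membrane_length_px))
        return DefectSpec(kind, location=(mid_row, stall_col))
    if kind is DefectKind.MEMBRANE_BRIGHT_SPOT:
        col = (c0 + geometry.test_line_center) // 2
        return DefectSpec(kind, location=(mid_row, col), size_px=10,
                          magnitude_adu=1800.0)
    center = geometry.test_line_center
    if kind is DefectKind.LINE_BRIGHT_PATCH:
        return DefectSpec(kind, location=(mid_row, center), size_px=8,
                          magnitude_adu=1100.0)
    return DefectSpec(kind, location=(mid_row, center), size_px=8,
                      magnitude_adu=1100.0)


def _square_footprint(defect: DefectSpec, geometry: StripGeometry
                      ) -> tuple[slice, slice]:
    if defect.location is None or defect.size_px <= 0:
        raise ValueError(f"{defect.kind.value} needs a location and size_px")
    row, col = defect.location
    half = defect.size_px // 2
    r0, r1 = row - half, row - half + defect.size_px
    c0, c1 = col - half, col - half + defect.size_px
    if r0 < 0 or c0 < 0 or r1 > geometry.image_height_px or \
            c1 > geometry.image_width_px:
        raise ValueError(f"defect footprint of {defect.kind.value} "
                         "lies outside the image")
    return slice(r0, r1), slice(c0, c1)


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free mean image plus exact labels at one time point."""

    t: float
    mean_image: np.ndarray            # float64, canonical orientation applied
    front_px: float                   # nominal front travel, clamped to membrane
    front_per_row: np.ndarray         # per-membrane-row front travel (px)
    line_masks: dict[str, np.ndarray]     # boolean, keys "test"/"control"
    defect_masks: list[np.ndarray]        # boolean, one per injected defect


def _validate_defects(defects: list[DefectSpec], geometry: StripGeometry) -> None:
    for d in defects:
        if d.kind in (DefectKind.MEMBRANE_BRIGHT_SPOT,
                      DefectKind.LINE_BRIGHT_PATCH,
                      DefectKind.LINE_DARK_PATCH):
            _square_footprint(d, geometry)
        elif d.kind is DefectKind.STALLED_FLOW:
            if d.location is None:
                raise ValueError("stalled_flow needs a location (row, col)")
            col = d.location[1]
            c0, c1 = geometry.membrane_cols
            if not (c0 <= col <= c1):
                raise ValueError("stall column outside the membrane")
        elif d.kind is DefectKind.SKEWED_FLOW:
            if not (0 < d.size_px <= geometry.membrane_length_px):
                raise ValueError("skew lag must be within the membrane length")


def _render(geometry: StripGeometry, kinetics: KineticsParams,
            defects: list[DefectSpec], t: float) -> GroundTruth:
    """Mean image and labels in the canonical horizontal orientation."""
    _validate_defects(defects, geometry)
    h, w = geometry.image_height_px, geometry.image_width_px
    r0, r1 = geometry.membrane_rows
    c0, c1 = geometry.membrane_cols
    length = geometry.membrane_length_px
    width = geometry.membrane_width_px

    img = np.full((h, w), kinetics.background_level, dtype=np.float64)

    nominal = min(kinetics.front_position(t), float(length))
    front = np.full(width, nominal, dtype=np.float64)

    stall_travel = math.inf
    for d in defects:
        if d.kind is DefectKind.STALLED_FLOW and t >= d.onset_time_s:
            stall_travel = min(stall_travel, float(d.location[1] - c0))
        elif d.kind is DefectKind.SKEWED_FLOW and t >= d.onset_time_s:
            rows = np.arange(width, dtype=np.float64)
            lag = d.size_px * rows / max(width - 1, 1)
            front = np.minimum(front, float(length) - lag)
    front = np.clip(np.minimum(front, stall_travel), 0.0, None)

    cols = np.arange(length, dtype=np.float64)
    wet = cols[None, :] < front[:, None]          # (width, length)
    membrane = img[r0:r1, c0:c1]
    membrane[wet] = kinetics.flow_level

    sigma = geometry.line_width_px / 2.0
    line_masks: dict[str, np.ndarray] = {}
    half_max = sigma * math.sqrt(2.0 * math.log(2.0))
    for name, center, sat, tau in (
        ("test", geometry.test_line_center,
         kinetics.line_saturation_level_t, kinetics.tau_t),
        ("control", geometry.control_line_center,
         kinetics.line_saturation_level_c, kinetics.tau_c),
    ):
        mask = np.zeros((h, w), dtype=bool)
        t_arr = kinetics.arrival_time(center - c0)
        growth = 0.0
        if t_arr is not None and t > t_arr and min(front) > 0:
            growth = 1.0 - math.exp(-(t - t_arr) / tau)
        if growth > 0 and sat > 0:
            x = cols + c0 - center
            profile = sat * growth * np.exp(-(x * x) / (2.0 * sigma * sigma))
            membrane += profile[None, :] * wet
            core = np.abs(x) <= half_max
            mask[r0:r1, c0:c1] = core[None, :] & wet
        line_masks[name] = mask

    defect_masks: list[np.ndarray] = []
    for d in defects:
        mask = np.zeros((h, w), dtype=bool)
        if d.kind is DefectKind.MEMBRANE_BRIGHT_SPOT and t >= d.onset_time_s:
            rs, cs = _square_footprint(d, geometry)
            img[rs, cs] += d.magnitude_adu
            mask[rs, cs] = True
        elif d.kind in (DefectKind.LINE_BRIGHT_PATCH,
                        DefectKind.LINE_DARK_PATCH) and t >= d.onset_time_s:
            rs, cs = _square_footprint(d, geometry)
            sign = 1.0 if d.kind is DefectKind.LINE_BRIGHT_PATCH else -1.0
            img[rs, cs] += sign * d.magnitude_adu
            mask[rs, cs] = True
        elif d.kind is DefectKind.SKEWED_FLOW and t >= d.onset_time_s:
            mask[r0:r1, c0:c1] = ~wet & (cols[None, :] < length)
        elif d.kind is DefectKind.STALLED_FLOW and t >= d.onset_time_s:
            mask[r0:r1, c0:c1] = ~wet
        defect_masks.append(mask)

    np.clip(img, 0.0, float(ADC_MAX), out=img)

    if geometry.flow_axis is FlowAxis.VERTICAL:
        img = np.ascontiguousarray(img.T)
        line_masks = {k: np.ascontiguousarray(v.T) for k, v in line_masks.items()}
        defect_masks = [np.ascontiguousarray(m.T) for m in defect_masks]

    return GroundTruth(t=t, mean_image=img, front_px=float(min(front.max(),
                                                               length)),
                       front_per_row=front, line_masks=line_masks,
                       defect_masks=defect_masks)


def ground_truth(geometry: StripGeometry, kinetics: KineticsParams,
                 defects: list[DefectSpec] | None = None,
                 t: float = 0.0) -> GroundTruth:
    """Noiseless mean image and exact labels at time ``t`` seconds."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return _render(geometry, kinetics, list(defects or []), t)


def generate_stack(geometry: StripGeometry, kinetics: KineticsParams,
                   defects: list[DefectSpec] | None = None,
                   duration_s: float = 360.0, interval_s: float = 20.0,
                   burst_size: int = 5, seed: int = 0) -> FrameStack:
    """Simulate a time-lapse acquisition of one cartridge.

    Bursts of ``burst_size`` frames are captured every ``interval_s``
    seconds starting at t = 0; frames within a burst share the burst
    timestamp and differ only by independent Poisson shot noise with
    per-pixel mean equal to the noiseless image.  Identical seeds give
    identical stacks.
    """
    if interval_s <= 0:
        raise ValueError("interval_s must be positive")
    if burst_size < 1:
        raise ValueError("burst_size must be >= 1")
    if duration_s < interval_s:
        raise ValueError("duration_s must cover at least one interval")
    defects = list(defects or [])
    _validate_defects(defects, geometry)

    n_bursts = math.ceil(duration_s / interval_s)
    rng = np.random.default_rng(seed)
    frames, timestamps, burst_index = [], [], []
    for b in range(n_bursts):
        t = b * interval_s
        mean = _render(geometry, kinetics, defects, t).mean_image
        noisy = rng.poisson(mean, size=(burst_size,) + mean.shape)
        np.clip(noisy, 0, ADC_MAX, out=noisy)
        for f in noisy:
            frames.append(f.astype(np.uint16))
            timestamps.append(float(t))
            burst_index.append(b)
    return FrameStack(frames=np.stack(frames),
                      timestamps=np.asarray(timestamps, dtype=np.float64),
                      burst_index=np.asarray(burst_index, dtype=np.int64),
                      resolution_px_per_mm=geometry.resolution_px_per_mm)
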