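"""Abnormality screening: skew, stalled flow, stray spots, line defects.

Local (adaptive) thresholding compares each pixel against the mean of
its w x w neighborhood: a pixel deviating from that local mean by more
than t percent is a defect candidate.  Dark deviants reveal unwetted
regions (skewed flow) and dark patches inside a line; bright deviants
reveal bright patches.  Stray bright blobs on the membrane are caught
by the line segmentation itself (more than two components, or a
component whose centroid matches neither expected line center), and a
stalled flow by a front that stabilizes short of the membrane end.

Detector performance is summarized with the usual confusion-matrix
metrics, where "positive" = a proper cartridge classified proper:

    sensitivity = 100 * TP / (TP + FN)
    specificity = 100 * TN / (TN + FP)
    accuracy    = 100 * (TP + TN) / (TP + FP + TN + FN)
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import binary_fill_holes

from .flow import DEFAULT_MIN_AREA_MM2, Component, FlowRecord, label_components
from .reaction import LineSegmentation

__all__ = [
    "Polarity", "AdaptiveParams", "adaptive_threshold",
    "SkewResult", "detect_skew", "detect_stalled_flow",
    "SpotResult", "detect_membrane_spots",
    "LineDefectResult", "detect_line_defects",
    "QCReport", "ConfusionMatrix", "Metrics", "classification_metrics",
]


class Polarity(str, enum.Enum):
    DARK_FOREGROUND = "dark_foreground"
    BRIGHT_FOREGROUND = "bright_foreground"


@dataclass(frozen=True)
class AdaptiveParams:
    """Neighborhood size and relative deviation threshold.

    ``t_percent`` is the deviation from the local mean, as a percentage
    of that mean, beyond which a pixel counts as deviant.
    """

    window: int = 15
    t_percent: float = 20.0

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        if not (0 < self.t_percent < 100):
            raise ValueError("t_percent must be in (0, 100)")


def _window_sums(image: np.ndarray, window: int) -> np.ndarray:
    """Exact w x w box sums centered per pixel, borders edge-replicated.

    Uses an integral image, so sums of integer-valued inputs are exact
    in float64 (well below 2**53).
    """
    k = window // 2
    padded = np.pad(np.asarray(image, dtype=np.float64), k, mode="edge")
    integral = padded.cumsum(axis=0).cumsum(axis=1)
    integral = np.pad(integral, ((1, 0), (1, 0)))
    w = window
    return (integral[w:, w:] - integral[:-w, w:]
            - integral[w:, :-w] + integral[:-w, :-w])


def adaptive_threshold(image: np.ndarray, params: AdaptiveParams,
                       polarity: Polarity | str = Polarity.DARK_FOREGROUND,
                       ) -> np.ndarray:
    """Binary map of pixels deviating from their local mean by > t%.

    ``dark_foreground`` marks pixels below mean*(1 - t/100) — the
    already-inverted map, so defects are foreground; ``bright_foreground``
    marks pixels above mean*(1 + t/100).  A uniform image yields an
    all-zero map in either polarity (every pixel equals its local mean).
    """
    polarity = Polarity(polarity)
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    if params.window > min(image.shape):
        raise ValueError("window larger than image")
    sums = _window_sums(image, params.window)
    n = params.window * params.window
    # cross-multiplied comparison: exact for integer-valued images
    if polarity is Polarity.DARK_FOREGROUND:
        return image * (100.0 * n) < sums * (100.0 - params.t_percent)
    return image * (100.0 * n) > sums * (100.0 + params.t_percent)


def _drop_corner_components(comps, shape: tuple[int, int]) -> np.ndarray:
    """Foreground with components containing a map corner pixel removed.

    Corner-touching segments come from the dark frame border around the
    cartridge window, not from the membrane itself.
    """
    labels = comps.labels
    h, w = shape
    corner_labels = {labels[0, 0], labels[0, w - 1],
                     labels[h - 1, 0], labels[h - 1, w - 1]} - {0}
    keep = labels > 0
    for lab in corner_labels:
        keep &= labels != lab
    return keep


@dataclass(frozen=True)
class SkewResult:
    flag: bool
    area_fraction: float
    mask: np.ndarray


def detect_skew(flow_frame: np.ndarray,
                params: AdaptiveParams = AdaptiveParams(window=61),
                area_fraction_threshold: float = 0.05,
                min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
                resolution_px_per_mm: float = 140.0) -> SkewResult:
    """Flag a skewed (partially unwetted) flow on the membrane crop.

    Dark-foreground adaptive thresholding marks unwetted pixels; after
    dot-pixel filtering and corner-segment trimming, the remaining
    foreground area is compared with the 5% (default) of the map size.
    The window should be comparable to the membrane width so the local
    mean can see across a dry wedge.
    """
    dark = adaptive_threshold(flow_frame, params, Polarity.DARK_FOREGROUND)
    comps = label_components(dark, min_area_mm2, resolution_px_per_mm)
    mask = _drop_corner_components(comps, dark.shape)
    frac = float(mask.sum()) / dark.size
    return SkewResult(flag=frac > area_fraction_threshold,
                      area_fraction=frac, mask=mask)


def detect_stalled_flow(records: Sequence[FlowRecord],
                        membrane_end_col: int,
                        stall_tolerance_px: int = 2,
                        persistence_frames: int = 3) -> bool:
    """True iff the front stops short of the membrane end.

    Uses the same persistence rule as flow-reached detection: both FL
    and the segment's far edge must be stable over the persistence
    window (the front has truly stopped, not merely one row of it),
    with the far edge short of the end by more than the tolerance.
    """
    if len(records) < 2:
        raise ValueError("need at least two flow records")
    if len(records) <= persistence_frames:
        return False
    fl = [r.fl_px for r in records]
    edge = [r.far_edge_col for r in records]
    for i in range(len(records) - persistence_frames):
        if fl[i] == 0 or edge[i] is None:
            continue
        window = range(persistence_frames)
        stable = all(abs(fl[i + j + 1] - fl[i + j]) <= stall_tolerance_px
                     for j in window) and \
            all(edge[i + j + 1] is not None
                and abs(edge[i + j + 1] - edge[i + j]) <= stall_tolerance_px
                for j in window)
        if stable and membrane_end_col - edge[i] > stall_tolerance_px:
            return True
    return False


@dataclass(frozen=True)
class SpotResult:
    flag: bool
    n_components: int
    anomalous: tuple[Component, ...]


def detect_membrane_spots(seg: LineSegmentation,
                          expected_line_centers: Sequence[float],
                          tolerance_px: float = 24.0,
                          vertical_axis: bool = False) -> SpotResult:
    """Flag stray bright components on the membrane.

    A retained component whose centroid along the flow axis is farther
    than ``tolerance_px`` from every expected line center is anomalous;
    the cartridge is also flagged when more than two components remain.
    """
    axis = 0 if vertical_axis else 1
    anomalous = tuple(
        c for c in seg.components
        if all(abs(c.centroid[axis] - e) > tolerance_px
               for e in expected_line_centers))
    flag = bool(anomalous) or len(seg.components) > 2
    return SpotResult(flag=flag, n_components=len(seg.components),
                      anomalous=anomalous)


@dataclass(frozen=True)
class LineDefectResult:
    bright_flag: bool
    dark_flag: bool
    bright_mask: np.ndarray
    dark_mask: np.ndarray


def detect_line_defects(seg: LineSegmentation,
                        params: AdaptiveParams = AdaptiveParams(),
                        min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
                        resolution_px_per_mm: float = 140.0,
                        ) -> LineDefectResult:
    """Flag bright/dark patches inside the test and control lines.

    Adaptive thresholding runs on the membrane in both polarities; the
    deviant maps are restricted to each line's own pixel set and
    dot-pixel filtered.  Ideally zero components remain; any survivor
    raises the corresponding flag.  Line masks are hole-filled first: a
    dark patch depressed below the reaction threshold punches a hole in
    its own line component and would otherwise escape inspection.
    """
    if seg.test is None:
        raise ValueError("no line components to inspect")
    line_mask = np.zeros_like(seg.filtered_map)
    for comp in (seg.test, seg.control):
        if comp is not None:
            line_mask |= binary_fill_holes(seg.component_mask(comp))

    masks, flags = {}, {}
    for pol in (Polarity.BRIGHT_FOREGROUND, Polarity.DARK_FOREGROUND):
        deviant = adaptive_threshold(seg.membrane, params, pol) & line_mask
        comps = label_components(deviant, min_area_mm2, resolution_px_per_mm)
        masks[pol] = comps.foreground
        flags[pol] = len(comps.components) > 0
    return LineDefectResult(
        bright_flag=flags[Polarity.BRIGHT_FOREGROUND],
        dark_flag=flags[Polarity.DARK_FOREGROUND],
        bright_mask=masks[Polarity.BRIGHT_FOREGROUND],
        dark_mask=masks[Polarity.DARK_FOREGROUND])


@dataclass
class QCReport:
    """Per-stack abnormality flags with supporting evidence."""

    skewed_flow: bool = False
    stalled_flow: bool = False
    extra_membrane_components: bool = False
    line_bright_defect: bool = False
    line_dark_defect: bool = False
    flow_reached_s: float | None = None
    skew_area_fraction: float | None = None
    n_line_components: int | None = None
    anomalous_centroids: list[tuple[float, float]] = field(default_factory=list)

    @property
    def flags(self) -> dict[str, bool]:
        return {"skewed_flow": self.skewed_flow,
                "stalled_flow": self.stalled_flow,
                "extra_membrane_components": self.extra_membrane_components,
                "line_bright_defect": self.line_bright_defect,
                "line_dark_defect": self.line_dark_defect}

    @property
    def verdict(self) -> str:
        return "improper" if any(self.flags.values()) else "proper"

    def to_dict(self) -> dict:
        return {"flags": self.flags, "verdict": self.verdict,
                "flow_reached_s": self.flow_reached_s,
                "skew_area_fraction": self.skew_area_fraction,
                "n_line_components": self.n_line_components,
                "anomalous_centroids": [list(c) for c in
                                        self.anomalous_centroids]}


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class Metrics:
    """Percentages at full precision plus integer-rounded for reports."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None

    @property
    def rounded(self) -> dict[str, int | None]:
        return {k: None if v is None else _round_half_up(v)
                for k, v in (("sensitivity", self.sensitivity),
                             ("specificity", self.specificity),
                             ("accuracy", self.accuracy))}


def classification_metrics(cm: ConfusionMatrix) -> Metrics:
    """Sensitivity/specificity/accuracy in percent.

    A metric whose denominator is zero is reported as None; an all-zero
    matrix is rejected.
    """
    if cm.total == 0:
        raise ValueError("all-zero confusion matrix")
    sens = 100.0 * cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else None
    spec = 100.0 * cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp > 0 else None
    acc = 100.0 * (cm.tp + cm.tn) / cm.total
    return Metrics(sensitivity=sens, specificity=spec, accuracy=acc)
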