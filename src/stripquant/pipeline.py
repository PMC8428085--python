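"""End-to-end orchestration of the analysis stages for one stack.

Stages (in order): burst averaging -> flow segmentation and tracking ->
flow-reached decision -> membrane ROI freeze -> line segmentation and
VR tracking -> abnormality screening.  Each stage is an importable
function; the CLI is a thin wrapper around these.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .flow import FlowRecord, detect_flow_reached, track_stack
from .io import AveragedFrame, FrameStack, average_stack
from .membrane import MembraneROI, crop, membrane_roi
from .qc import (AdaptiveParams, QCReport, detect_line_defects,
                 detect_membrane_spots, detect_skew, detect_stalled_flow)
from .reaction import (LineSegmentation, ReactionSeries, RegionMeasurement,
                       measure_regions, segment_lines)
from .synthetic import KineticsParams, StripGeometry

__all__ = ["FlowAnalysis", "config_for", "default_rt",
           "analyze_flow", "quantify_reaction", "run_qc"]


def default_rt(kinetics: KineticsParams) -> float:
    """Reaction threshold for synthetic stacks: midpoint between the
    wetted-membrane background and the test line's saturated peak."""
    return kinetics.flow_level + 0.5 * kinetics.line_saturation_level_t


def config_for(geometry: StripGeometry, kinetics: KineticsParams,
               **overrides) -> RunConfig:
    """A RunConfig carrying the cartridge geometry a real deployment
    would take from the kit datasheet."""
    cfg = RunConfig(
        resolution_px_per_mm=geometry.resolution_px_per_mm,
        rt=default_rt(kinetics),
        flow_axis=geometry.flow_axis.value,
        expected_line_centers=(float(geometry.test_line_center),
                               float(geometry.control_line_center)),
        membrane_end_col=geometry.membrane_cols[1],
    )
    return cfg.with_overrides(**overrides)


def _canonical_frames(stack: FrameStack, config: RunConfig
                      ) -> list[AveragedFrame]:
    """Averaged frames, transposed to horizontal flow if needed."""
    frames = average_stack(stack)
    if config.vertical_axis:
        frames = [AveragedFrame(pixels=np.ascontiguousarray(f.pixels.T),
                                t=f.t) for f in frames]
    return frames


@dataclass
class FlowAnalysis:
    frames: list[AveragedFrame]          # canonical orientation
    records: list[FlowRecord]
    t_reached_s: float | None
    roi: MembraneROI | None


def analyze_flow(stack: FrameStack, config: RunConfig) -> FlowAnalysis:
    """Track the flow and, when it reaches the membrane end, freeze the
    membrane ROI from that frame's flow map."""
    frames = _canonical_frames(stack, config)
    records = track_stack(frames, config.resolution_px_per_mm,
                          config.min_area_mm2,
                          config.histogram_smoothing_window)
    t_reached, roi = None, None
    if config.membrane_end_col is not None \
            and len(records) > config.persistence_frames:
        t_reached = detect_flow_reached(records, config.membrane_end_col,
                                        config.stall_tolerance_px,
                                        config.persistence_frames)
    if t_reached is not None:
        idx = next(i for i, r in enumerate(records) if r.t == t_reached)
        roi = membrane_roi(records[idx].flow_map,
                           config.resolution_px_per_mm)
    return FlowAnalysis(frames=frames, records=records,
                        t_reached_s=t_reached, roi=roi)


def _segment_frame(frame: AveragedFrame, roi: MembraneROI,
                   config: RunConfig) -> LineSegmentation:
    return segment_lines(crop(frame, roi), config.require_rt(),
                         config.min_area_mm2, config.resolution_px_per_mm,
                         reverse_flow=config.reverse_flow)


def quantify_reaction(stack: FrameStack, config: RunConfig,
                      flow: FlowAnalysis | None = None
                      ) -> tuple[ReactionSeries, FlowAnalysis]:
    """Per-timepoint AT/AC/VT/VC/AR/VR for one stack.

    Measurements before the flow-reached time are recorded as zeros
    (the lines have not formed while the sample is still flowing).
    """
    flow = flow or analyze_flow(stack, config)
    measurements = []
    for frame in flow.frames:
        if flow.t_reached_s is None or frame.t < flow.t_reached_s \
                or flow.roi is None:
            measurements.append(RegionMeasurement(
                t=frame.t, at=0, ac=0, vt=0.0, vc=0.0, ar=0.0, vr=0.0))
        else:
            seg = _segment_frame(frame, flow.roi, config)
            measurements.append(measure_regions(seg, t=frame.t))
    return ReactionSeries(measurements=measurements), flow


def run_qc(stack: FrameStack, config: RunConfig,
           flow: FlowAnalysis | None = None) -> QCReport:
    """Full abnormality screen for one stack.

    Skew is checked on the membrane crop of the flow-reached frame
    (before the lines brighten enough to bias the local mean); stray
    spots and in-line defects on the final frame.  When the flow never
    reaches the membrane end, only flow-related checks run.
    """
    if config.membrane_end_col is None:
        raise ValueError("config.membrane_end_col is required for QC")
    flow = flow or analyze_flow(stack, config)
    report = QCReport(flow_reached_s=flow.t_reached_s)
    report.stalled_flow = detect_stalled_flow(
        flow.records, config.membrane_end_col,
        config.stall_tolerance_px, config.persistence_frames)

    if flow.t_reached_s is None or flow.roi is None:
        if not report.stalled_flow:
            # never stabilized within the acquisition window
            report.stalled_flow = True
        return report

    roi = flow.roi
    reached_frame = next(f for f in flow.frames if f.t == flow.t_reached_s)
    skew = detect_skew(crop(reached_frame, roi),
                       AdaptiveParams(config.skew_window,
                                      config.skew_t_percent),
                       config.skew_area_fraction, config.min_area_mm2,
                       config.resolution_px_per_mm)
    report.skewed_flow = skew.flag
    report.skew_area_fraction = skew.area_fraction

    final = flow.frames[-1]
    seg = _segment_frame(final, roi, config)
    report.n_line_components = len(seg.components)
    if config.expected_line_centers is not None:
        centers = [c - roi.col0 for c in config.expected_line_centers]
        spots = detect_membrane_spots(seg, centers)
        report.extra_membrane_components = spots.flag
        report.anomalous_centroids = [c.centroid for c in spots.anomalous]
    if seg.test is not None:
        defects = detect_line_defects(
            seg, AdaptiveParams(config.adaptive_window,
                                config.adaptive_t_percent),
            config.min_area_mm2, config.resolution_px_per_mm)
        report.line_bright_defect = defects.bright_flag
        report.line_dark_defect = defects.dark_flag
    return report
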