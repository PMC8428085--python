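"""Adaptive thresholding and the abnormality detectors."""

import numpy as np
import pytest

import stripquant as sq
from stripquant.qc import AdaptiveParams, Polarity, _round_half_up


# --- adaptive thresholding -------------------------------------------------

def _brute_force_adaptive(image, window, t_percent, polarity):
    """Independent O(n*w^2) oracle with exact integer comparisons."""
    h, w = image.shape
    k = window // 2
    n = window * window
    out = np.zeros((h, w), bool)
    for i in range(h):
        for j in range(w):
            s = 0
            for di in range(-k, k + 1):
                for dj in range(-k, k + 1):
                    ii = min(max(i + di, 0), h - 1)   # edge replication
                    jj = min(max(j + dj, 0), w - 1)
                    s += int(image[ii, jj])
            if polarity == "dark_foreground":
                out[i, j] = int(image[i, j]) * 100 * n < s * (100 - t_percent)
            else:
                out[i, j] = int(image[i, j]) * 100 * n > s * (100 + t_percent)
    return out


def test_uniform_image_has_no_deviants():
    img = np.full((12, 12), 1000.0)
    for pol in Polarity:
        assert not sq.adaptive_threshold(img, AdaptiveParams(5, 20.0),
                                         pol).any()


def test_single_dark_pixel_flagged():
    img = np.full((11, 11), 1000.0)
    img[5, 5] = 0.0
    dark = sq.adaptive_threshold(img, AdaptiveParams(5, 20.0),
                                 Polarity.DARK_FOREGROUND)
    assert dark[5, 5]
    oracle = _brute_force_adaptive(img, 5, 20.0, "dark_foreground")
    assert np.array_equal(dark, oracle)


@pytest.mark.parametrize("window", [3, 5, 7])
@pytest.mark.parametrize("polarity", ["dark_foreground", "bright_foreground"])
def test_adaptive_matches_sliding_window_oracle(window, polarity, rng):
    img = rng.integers(0, 4096, size=(15, 15)).astype(np.int64)
    ours = sq.adaptive_threshold(img, AdaptiveParams(window, 20.0), polarity)
    assert np.array_equal(ours, _brute_force_adaptive(img, window, 20.0,
                                                      polarity))


def test_window_larger_than_image_rejected():
    with pytest.raises(ValueError, match="window"):
        sq.adaptive_threshold(np.zeros((5, 5)), AdaptiveParams(7, 20.0))


def test_adaptive_params_validated():
    with pytest.raises(ValueError):
        AdaptiveParams(window=4)
    with pytest.raises(ValueError):
        AdaptiveParams(t_percent=0.0)


# --- skew detection --------------------------------------------------------

def _membrane_crop_at_reached(geometry, kinetics, defects, seed):
    cfg = sq.config_for(geometry, kinetics)
    stack = sq.generate_stack(geometry, kinetics, defects,
                              duration_s=200, seed=seed)
    flow = sq.analyze_flow(stack, cfg)
    frame = next(f for f in flow.frames if f.t == flow.t_reached_s)
    return sq.crop(frame, flow.roi)


def test_clean_flow_frame_not_skewed(geometry, kinetics):
    crop = _membrane_crop_at_reached(geometry, kinetics, [], seed=21)
    assert not sq.detect_skew(crop).flag


def test_ten_percent_wedge_flagged(geometry, kinetics):
    # lag 80 px -> dry wedge = 80 * 80 / 2 = 3200 px = 10% of the crop
    wedge = sq.DefectSpec(sq.DefectKind.SKEWED_FLOW, size_px=80)
    crop = _membrane_crop_at_reached(geometry, kinetics, [wedge], seed=22)
    res = sq.detect_skew(crop)
    assert res.flag
    assert res.area_fraction > 0.05


def test_three_percent_wedge_not_flagged(geometry, kinetics):
    wedge = sq.DefectSpec(sq.DefectKind.SKEWED_FLOW, size_px=24)
    crop = _membrane_crop_at_reached(geometry, kinetics, [wedge], seed=23)
    assert not sq.detect_skew(crop).flag


# --- stalled flow ----------------------------------------------------------

def _records(fl_and_edges):
    return [sq.FlowRecord(t=20.0 * i, fl_px=fl, fw_px=10, fa_px2=fl,
                          fl_mm=0, fw_mm=0, fa_mm2=0, bbox=(0, 10, 0, edge))
            for i, (fl, edge) in enumerate(fl_and_edges)]


def test_stalled_defect_detected(geometry, kinetics, config):
    stall = sq.default_defect("stalled_flow", geometry)
    stack = sq.generate_stack(geometry, kinetics, [stall],
                              duration_s=200, seed=31)
    flow = sq.analyze_flow(stack, config)
    assert sq.detect_stalled_flow(flow.records, config.membrane_end_col)


def test_normal_flow_not_stalled(clean_flow, config):
    assert not sq.detect_stalled_flow(clean_flow.records,
                                      config.membrane_end_col)


def test_front_stopping_exactly_at_end_not_stalled():
    recs = _records([(100, 100), (300, 300), (400, 400),
                     (400, 400), (400, 400), (400, 400)])
    assert not sq.detect_stalled_flow(recs, membrane_end_col=400)
    # one pixel short of tolerance is still fine
    recs = _records([(398, 398)] * 6)
    assert not sq.detect_stalled_flow(recs, membrane_end_col=400)
    recs = _records([(300, 300)] * 6)
    assert sq.detect_stalled_flow(recs, membrane_end_col=400)


# --- membrane spots --------------------------------------------------------

def _seg_from_rectangles(rects, shape=(40, 200), level=2000.0):
    img = np.zeros(shape)
    for (r0, r1, c0, c1) in rects:
        img[r0:r1, c0:c1] = level
    return sq.segment_lines(img, rt=1000.0, resolution_px_per_mm=10.0)


def test_expected_lines_not_flagged_as_spots():
    seg = _seg_from_rectangles([(10, 30, 55, 65), (10, 30, 135, 145)])
    res = sq.detect_membrane_spots(seg, expected_line_centers=[60, 140],
                                   tolerance_px=10)
    assert not res.flag


def test_third_component_flagged_with_its_centroid():
    seg = _seg_from_rectangles([(10, 30, 55, 65), (10, 30, 135, 145),
                                (15, 25, 95, 105)])
    res = sq.detect_membrane_spots(seg, expected_line_centers=[60, 140],
                                   tolerance_px=10)
    assert res.flag and len(res.anomalous) == 1
    assert res.anomalous[0].centroid[1] == pytest.approx(99.5, abs=0.5)


def test_displaced_component_flagged_by_centroid_rule():
    seg = _seg_from_rectangles([(10, 30, 55, 65), (10, 30, 95, 105)])
    res = sq.detect_membrane_spots(seg, expected_line_centers=[60, 140],
                                   tolerance_px=10)
    assert res.flag


def test_injected_bright_spot_detected_end_to_end(geometry, kinetics, config):
    spot = sq.default_defect("membrane_bright_spot", geometry)
    stack = sq.generate_stack(geometry, kinetics, [spot],
                              duration_s=300, seed=41)
    report = sq.run_qc(stack, config)
    assert report.extra_membrane_components
    assert report.verdict == "improper"


# --- in-line defects -------------------------------------------------------

def _line_defect_run(geometry, kinetics, config, kind, seed):
    defect = sq.default_defect(kind, geometry)
    stack = sq.generate_stack(geometry, kinetics, [defect],
                              duration_s=360, seed=seed)
    flow = sq.analyze_flow(stack, config)
    seg = sq.segment_lines(sq.crop(flow.frames[-1], flow.roi), config.rt)
    truth = sq.ground_truth(geometry, kinetics, [defect], t=flow.frames[-1].t)
    defect_mask = truth.defect_masks[0][flow.roi.row0:flow.roi.row1,
                                        flow.roi.col0:flow.roi.col1]
    return sq.detect_line_defects(seg), defect_mask


def test_clean_lines_have_no_defect_flags(clean_flow, config):
    seg = sq.segment_lines(sq.crop(clean_flow.frames[-1], clean_flow.roi),
                           config.rt)
    res = sq.detect_line_defects(seg)
    assert not res.bright_flag and not res.dark_flag


def test_dark_patch_flagged_with_overlapping_mask(geometry, kinetics, config):
    res, truth_mask = _line_defect_run(geometry, kinetics, config,
                                       "line_dark_patch", seed=51)
    assert res.dark_flag
    overlap = (res.dark_mask & truth_mask).sum() / truth_mask.sum()
    assert overlap >= 0.5


def test_bright_patch_flagged(geometry, kinetics, config):
    res, truth_mask = _line_defect_run(geometry, kinetics, config,
                                       "line_bright_patch", seed=52)
    assert res.bright_flag
    overlap = (res.bright_mask & truth_mask).sum() / truth_mask.sum()
    assert overlap >= 0.5


def test_line_defects_require_lines():
    seg = sq.segment_lines(np.zeros((20, 60)), rt=100.0)
    with pytest.raises(ValueError, match="no line components"):
        sq.detect_line_defects(seg)


# --- classification metrics ------------------------------------------------

def test_perfect_flow_screen_metrics():
    m = sq.classification_metrics(sq.ConfusionMatrix(tp=10, fp=0, tn=6, fn=0))
    assert (m.sensitivity, m.specificity, m.accuracy) == (100.0, 100.0, 100.0)


def test_membrane_screen_metrics():
    m = sq.classification_metrics(sq.ConfusionMatrix(tp=116, fp=1, tn=9, fn=4))
    assert m.specificity == pytest.approx(90.0)
    assert m.accuracy == pytest.approx(100 * 125 / 130)   # 96.15...
    assert m.rounded["accuracy"] == 96
    assert m.sensitivity == pytest.approx(100 * 116 / 120)


def test_undefined_metric_is_none_and_all_zero_rejected():
    m = sq.classification_metrics(sq.ConfusionMatrix(tp=0, fp=0, tn=5, fn=0))
    assert m.sensitivity is None and m.specificity == 100.0
    with pytest.raises(ValueError):
        sq.classification_metrics(sq.ConfusionMatrix(0, 0, 0, 0))


def test_report_rounding_is_half_up():
    assert _round_half_up(96.15) == 96
    assert _round_half_up(96.5) == 97
    assert _round_half_up(89.5) == 90


def test_verdict_improper_iff_any_flag():
    rep = sq.QCReport()
    assert rep.verdict == "proper"
    rep.line_dark_defect = True
    assert rep.verdict == "improper"
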