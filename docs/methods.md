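# Methods

This note documents the models behind `stripquant`, the parameter
choices that matter, what the synthetic-strip generator does and does
not emulate, and the numerical conventions used throughout.

## Imaging model

The reader observes a static strip with a 12-bit camera (ADU range
0–4095).  Acquisition is burst-mode: every `capture_interval_s`
(default 20 s) a burst of `burst_size` frames (default 5) is captured;
frames within a burst share one timestamp and differ only by photon
shot noise.  Because shot noise is Poisson with variance equal to the
mean, the burst average I(t) has its noise suppressed by 1/√n while
the mean is unchanged; averaged values are kept as reals (never
re-quantized) so that summed line intensities VT/VC are unbiased.
Stacks are stored as 16-bit unsigned TIFFs (lossless container for the
12-bit range) plus a CSV manifest (`frame_path`, `burst`,
`timestamp_s`, `resolution_px_per_mm`).

## Flow segmentation

Each averaged frame is binarized with a global threshold taken from its
own histogram: 256 bins over [0, 4096), smoothed by a centered moving
average (window 5 bins), dominant peak = global maximum bin (the
background dominates the field of view), threshold = bin center of the
deepest local minimum after that peak, ties broken toward lower
intensity.  If no local minimum exists after the peak (e.g. the frame
is almost saturated), the midpoint between the peak and the range
maximum is used and flagged as a fallback.  Thresholding is strictly
`>`; components are 8-connected; the dot-pixel filter keeps components
strictly larger than `min_area_mm2 · resolution²` (0.003 mm² at
140 px/mm ⇒ 58.8 px, so 58-px blobs drop and 59-px blobs survive).
The largest surviving component is the flow segment; FL/FW are pixel
counts in the bounding box's middle row/column (floor(extent/2) for
even extents), FA the total count.  Coordinates are 0-based, row-major;
bounding boxes half-open.

**Flow reached.** The reaction is tracked relative to the time the
front reaches the visible membrane end.  Neither FL stabilization nor
edge contact alone is reliable (a stalled front also stabilizes; a
noisy edge can touch briefly), so both are required: |ΔFL| ≤
`stall_tolerance_px` (default 2) for `persistence_frames` (default 3)
consecutive intervals, with the segment's far edge within the same
tolerance of the membrane end.  The membrane-end coordinate is
cartridge geometry and comes from the configuration — the image alone
cannot distinguish "reached" from "stalled just short".  A stalled
flow is the complementary event: FL *and* the far edge stable while
the front is short of the end by more than the tolerance.

## Line quantification and stability

The membrane crop is thresholded at the reaction threshold RT
(strictly `>`), area-filtered as above, and the surviving components
ordered by centroid along the flow axis: upstream = test, next =
control (`reverse_flow` flips this for mirrored cartridges).  RT is an
experimentally determined lot constant with no universal default; for
synthetic data the pipeline uses the midpoint between the wetted
membrane level and the test line's saturated peak.  AT/AC are
component pixel counts; VT/VC sum the segmented image SI(t) =
NCM(t)·AFB(t); AR/VR are recorded as 0 whenever the control
denominator is 0 (during sample flow, before the lines form).

VR slopes are per-interval finite differences in VR per **minute**.
The stability time is the earliest capture tick at which the fraction
of samples with |slope| ≤ `stability_band` reaches
`stability_fraction` (default 0.95) *and remains so at every later
tick* — the persistence clause prevents a transient dip into the band
from counting.  The band half-width is assay-specific configuration
(sandwich-type assays with VR of order 5 use ±0.5 VR/min; low-VR
competitive assays a proportionally smaller band); it is never
hardcoded.  Single-sample stability is supported (the fraction is then
0 or 1).

Note a measurement artifact inherent to threshold segmentation: as a
line brightens, its component widens in whole pixel columns, so the
thresholded VR series carries small quantization jumps (a few percent)
on top of the smooth kinetics.  Tests of the saturating-kinetics shape
therefore freeze the line masks at readout time.

## QC detectors

Adaptive thresholding compares each pixel with its w×w local mean
(edge-replicated borders, computed exactly via an integral image):
dark-deviant iff value < µ·(1 − t/100), bright-deviant iff value >
µ·(1 + t/100), with t the relative deviation percentage (default 20).
The deviation is relative to the local mean, not an absolute ADU
offset.

* **Skew** runs dark-foreground on the membrane crop of the
  flow-reached frame.  Window default 61 px (≈ the membrane width):
  the local mean must see across the dry wedge, which a line-scaled
  window cannot; the frame choice matters because later frames have
  brighter lines whose halo depresses the relative deviation of
  neighboring membrane pixels.  After dot-pixel filtering, components
  containing a literal corner pixel of the map are trimmed (they stem
  from the dark surround of the cartridge window, not the membrane);
  the remaining foreground area is compared against
  `skew_area_fraction` (default 5%) of the map.
* **Stray spots**: after line segmentation, any component whose
  centroid along the flow axis is farther than a tolerance (default
  24 px, one line width) from both expected line centers is anomalous;
  more than two components also flags.
* **In-line defects** run both adaptive polarities (window 15 px ≈ the
  line width, t = 20%) restricted to each line's own pixels.  Line
  masks are hole-filled first: a dark patch depressed below RT punches
  a hole in its own component and would otherwise escape inspection.
  Any component surviving the dot-pixel filter raises the flag; the
  area filter also makes the detectors immune to isolated shot-noise
  outliers.

A cartridge is `improper` iff any flag is raised.  Screen performance
uses sensitivity = 100·TP/(TP+FN), specificity = 100·TN/(TN+FP),
accuracy = 100·(TP+TN)/total, where "positive" is a proper cartridge
classified proper; percentages are reported at full precision plus
round-half-up integers.

## Calibration

`fit_calibration` is an ordinary least-squares fit of a configurable
form (linear default, quadratic, log-linear); the model records the
fitted VR range (predictions outside it warn), the residual sum of
squares, and the assay direction (decreasing conc-vs-VR for
competitive assays).  Relative error is 100·(predicted −
expected)/expected, reported to two decimals; a verification set
passes when max |error| ≤ the band (default 8%).

## Synthetic strip generator

The generator renders a noiseless mean image and adds independent
per-pixel Poisson noise with mean equal to that image (shot noise
only — no read-noise or dark-current term), clipped to [0, 4095].
It emulates:

* a front advancing as l(t) = v₀t − ½at² (linearly decaying speed,
  clamped at t = v₀/a and at the membrane end);
* test/control lines with Gaussian cross-profile (σ = line_width/2),
  uniform across the membrane width, growing as
  sat·(1 − e^−(t−t_arrive)/τ) once the front passes the line center;
* five defect types: skewed flow (persistent per-row front deficit
  leaving a dry wedge of lag·width/2 px), stalled flow (front clamped
  at an obstruction column), membrane bright spot, and bright/dark
  square patches inside a line.

Default study conditions (chosen once, as a scaled-down but
physically plausible cartridge, and used for every test and
acceptance study): 160×480 px image, membrane 80×400 px, 140 px/mm,
20 s bursts of 5 frames; v₀ = 6.8 px/s with a = v₀/120 so the front
reaches the membrane end at ≈103 s — inside the 1.5–2 min flow window
typical of these cartridges — and would stall at 120 s; background
100 ADU, wetted membrane 1600 ADU; line saturations 1500/1200 ADU with
τ = 180/240 s (test/control); line width 24 px; defect defaults: 80 px
skew lag (10% dry wedge), stall at 60% of the membrane, 10×10 px spot
at +1800 ADU, 8×8 px line patches at ±1100 ADU.  The intensity levels
were set so that every detector retains a ≥4σ shot-noise margin
against false flags at its operating frame while the documented defect
magnitudes clear their thresholds with similar margins.

Not emulated: optical point-spread, illumination non-uniformity, dye
spectra, membrane texture, read noise, or mechanical misalignment.
Passing tests therefore demonstrate the correctness and calibrated
sensitivity of the algorithms under the stated noise and kinetics
model, not robustness to every real-world imaging artifact.

## Acceptance studies and problem sizes

`scripts/acceptance.py` (all randomness derived from `--seed`):

* flow screen: 10 proper + 6 skewed cartridges at 200 s each;
* membrane screen: 12 proper + 10 defective (4 spots, 3 bright and 3
  dark patches) at 360 s each;
* calibration verification: the nine published reference
  expected/measured concentration pairs (six HbA1C, three vitamin D),
  max |relative error| = 7.62% against the 8% band;
* front recovery: one 240 s cartridge, max |FL − l(t)| and the
  speed-decay coefficient error from the least-squares slope of FS
  vs t;
* stability recovery: ten saturating VR series (V ∈ [5,7], τ ∈
  [2.5,3.5] min) on the 20 s grid, compared with the closed-form
  band-crossing time of the discrete trailing-window slope,
  t_c = τ·ln(V(e^(Δ/τ) − 1)/(Δ·band)).

The test suite mirrors these studies with 20 seeded replicates per
defect type and 20 defect-free stacks.  Stack durations (200–360 s)
and the scaled-down geometry were chosen so a full run remains cheap
while every stage (flow, reached, line development, readout) is
exercised.

## Known limitations

* The flow-front law is a modelling choice consistent with the
  observed linear speed decay; real membranes follow Washburn-type
  √t kinetics more closely at long times.
* Skew detection assumes the wedge is dark relative to a mostly-wetted
  membrane; a skew so severe that most of the crop is dry would be
  caught by the stalled/reached logic instead.
* The corner-trim rule ("component contains a corner pixel") is a
  deliberate, documented interpretation; alternatives (bounding-box
  contact) delete the wedge itself and were rejected.
* Vertical flow axes are handled by transposition at pipeline entry;
  membrane-end and line-center coordinates are always specified along
  the flow axis.
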