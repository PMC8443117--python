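# Methods

This note documents the models, conventions and numerical choices behind
`gaitpose`: what each stage assumes, which parameters matter, what the
synthetic generator does and does not emulate, and where genuinely open design
questions were settled.

## Data model and coordinate conventions

A `PoseTrajectory` stores per-frame 2D keypoints for the 17-joint COCO
skeleton plus a derived `MID_HIP` (mean of the hips; its confidence is the
minimum of the two hip confidences — a conservative propagation). Readers for
the OpenPose, AlphaPose and Detectron output formats reduce everything to
this common denominator: extra landmarks (BODY-25 mid-hip, toes) are dropped
and `MID_HIP` is always recomputed. Coordinates stay in image pixels, origin
top-left, y down-positive, exactly as in the source files; the single flip to
up-positive happens inside event detection. Timestamps are
`frame_index / frame_rate` (30 Hz for video, 100 Hz for reference-role
streams).

In multi-person frames the participant is chosen as the detection with the
largest keypoint bounding-box area; candidates within 5% of the largest are
tie-broken by continuity (nearest mid-hip to the previously selected
mid-hip). This is a stated convention — frontal walking recordings have the
participant centred and largest in frame — and it is deterministic.

## Preprocessing

The pipeline order is fixed and enforced: **mask/interpolate →
swap-correct → smooth → crop**. Smoothing precedes event detection.

**Confidence masking.** Observations with confidence below the
tracker-specific threshold (OpenPose 0.3, AlphaPose 0.5, Detectron 0.15 —
confidence scales are not calibrated across trackers) are replaced by linear
interpolation in time between the nearest flanking confident observations of
the same joint. Leading/trailing gaps hold the first/last confident value
rather than extrapolating: linear extrapolation amplifies tracker noise at
bout edges. A joint missing in ≥ 10% of frames fails the quality rule — the
boundary counts as failing — and the bout is flagged, not silently dropped.

**Left/right swap correction.** Per-frame pose estimators occasionally label
a left joint as its right counterpart. For each left/right pair, a frame's
labels are exchanged when the exchange reduces the mean distance to the
like-labelled joints of the neighbouring frames (offsets ±1 and ±2) by more
than 25% of the hip width at that frame. Two properties of this rule were
deliberate:

* decisions within a pass are computed from the current state and applied
  *simultaneously*. A sequential rule that compares each frame to the
  previously *corrected* frame was tried first and discarded: when a swap
  occurs at a frame where the two joints nearly coincide (mid-swing
  pass-by), it is undetectable at that frame, and the sequential feedback
  then inverts the labels of the entire remaining bout — tens of spurious
  "corrections" from a handful of real swaps, destroying strike detection.
  The feedback-free local rule cannot cascade; it fixes isolated swaps and
  runs of two (runs of three or more are vanishingly rare under realistic
  swap rates);
* passes repeat until no frame changes (≤ 4), which makes the operation
  idempotent, and genuine smooth crossings of the two tracks are left alone
  because exchanging them would not improve neighbour continuity beyond the
  margin.

A manual-override file of (frame, pair) exchanges is applied after the
automatic passes, preserving the escape hatch of visual inspection.

**Smoothing.** Zero-lag low-pass Butterworth, cutoff 8 Hz, order 2, applied
forward and backward (`filtfilt`; the effective attenuation is that of a
4th-order filter, the net phase is zero). Edge handling is reflective
padding of 3 × (order + 1) samples. The cutoff must lie below the Nyquist
frequency; trajectories shorter than the padded length are rejected.

**Bout cropping.** Straight-walking bouts (turns excluded) are an input
annotation file with 0-based inclusive frame bounds — manual in origin, no
automatic turn detection.

## Foot-strike detection

The ankle's vertical series is flipped up-positive and linearly detrended
over the bout. The dominant trend in frontal video is the monotone
perspective drift as the subject approaches or recedes; a linear least-squares
detrend (not a high-pass filter) removes most of it without distorting the
within-stride shape. Strikes are local minima of the detrended series — the
ankle is lowest around foot-flat. Two robustness guards:

* candidate minima closer than a minimum stride interval (default 0.6 s;
  safe up to 130 steps/min, where the stride is ~0.92 s) are merged keeping
  the lower one;
* minima with prominence below 10% of the detrended series' interquartile
  range are discarded.

Each accepted minimum gets parabolic sub-frame refinement (a parabola through
the minimum and its two neighbours, offset clamped to ±0.5 frames). At 30 fps
the quantization floor of ±1/60 s is a visible fraction of the step-time
variability; the refinement removes most of it while the event's integer
`frame_index` remains the anchor for all spatial reads.

"Local extrema" could also be read as maxima; the minima convention
(foot flat ≈ lowest ankle) is this package's decision and is configurable
only through the sign of the input.

**Cross-system alignment.** Video and reference strike sequences are matched
greedily by nearest time within a 0.25 s window (below half the shortest
plausible step time), preserving foot-label order, after removing a supplied
clock offset (zero for synthetic data). The matched subsequences are equal
length, so both systems measure the same physical steps; a step enters the
per-step tables only when both systems advanced by exactly one strike and
the feet alternate.

## Gait variables

Per step (between consecutive alternating-foot strikes): step time is the
strike-time difference; step width is the lateral distance between the two
ankles read at the step-ending strike frame. Per bout: cadence is
60 × (n − 1)/(t_last − t_first) over the strike sequence; CVs use the sample
(n − 1) standard deviation — bouts are small-n.

**Hip-width normalization.** Video spatial quantities are divided by the hip
width at the same frame (not a bout constant): perspective scale changes
within a bout, and the frame-local ratio cancels it exactly for a
fronto-parallel skeleton. Multiplying all pixel coordinates by any k > 0
leaves normalized step width and eMOS unchanged (verified as a property
test).

**eMOS.** `eMOS = XCOM − BOS` with `XCOM = COM + V_COM/ω`, `ω = √(g/l)`.
The video COM proxy is the lateral mid-hip (the reference uses the sacrum);
BOS is the stance-foot ankle's lateral position at the strike frame; V_COM is
the central finite difference of the smoothed COM series (one-sided at bout
edges). Three conventions matter:

* **ω in pixel space.** ω is a purely temporal quantity (1/s), computed in
  SI from the leg length in metres (default 0.53 × height when unmeasured, a
  standard anthropometric ratio). Dividing a velocity in hip-width units/s
  by the SI ω is unit-consistent and keeps video eMOS in hip-width units.
* **Centering before normalization.** Raw image x divided by hip width
  leaves a spurious trend: x = cx + s(t)·lateral while hip width = s(t)·w,
  so the image-centre offset cx becomes a time-varying additive term that
  corrupts V_COM. Lateral coordinates are therefore centred on the bout-mean
  mid-hip x before the frame-local division. Same-frame differences
  (step width, COM − BOS) are unaffected; the COM velocity becomes clean.
* **Sign.** The per-step lateral axis points from the stance foot toward the
  bout-mean COM line, so eMOS is positive when the extrapolated COM stays
  medial of the stance foot — the stable configuration. At reference scale
  this puts the mean eMOS at a few centimetres, about half the step width
  minus the XCOM excursion, consistent with motion-capture-scale values.

## Validation statistics

**Correlation grid.** 3 trackers × 2 cameras × 2 views × 2 methods = 24
cells; each cell holds a Pearson r, a two-sided p from the t transform on
n − 2 degrees of freedom, and n, per gait variable. "Individual steps" pools
every aligned step (bout-level quantities — cadence, the CVs — pair per
bout); "mean of all steps" averages per participant over all bouts of the
view before correlating, so n is the number of participants. No
multiple-testing correction is applied; α = 0.05 is a reporting-time
convention only. Cells with missing inputs are marked unavailable but the
grid keeps its 24-cell structure.

**Precision.** Within each tracker/camera/view group, the CV of each
participant's per-bout values, summarized as mean (SD) across participants.
Participants with fewer than two bouts contribute nothing; empty groups are
marked unavailable.

**Bland–Altman.** Pairwise tracker agreement on per-step values: mean
difference and limits of agreement at ±1.96 sample SD (the interval holding
~95% of Gaussian differences — verified by Monte Carlo). Temporal variables
are identical whenever the trackers' strike sequences agree, so the default
reports spatial variables (step width, eMOS) only; a flag adds the rest.

## The synthetic generator

The walker is kinematic, not dynamic — only the observation model matters
for testing the pipeline. Per bout: alternating-foot strike times with mean
step time 60/cadence and a within-bout CV; lateral foot placements at
±(step width)/2 with per-step Gaussian jitter; a lateral COM that follows a
natural cubic spline through zero at each strike and a sway excursion
(30% of the stance-foot lateral) at mid-stance; an ankle height of
lift·|sin(πu)| between consecutive same-foot strikes — zero exactly at each
strike, with a cusp-like minimum that a linear trend cannot displace, which
is what makes strike recovery well-posed under perspective drift. The
skeleton is fronto-parallel and projected through a pinhole camera,
f = 1200 px, walking between 15 m and 6 m from the camera; the 2.05 m "top"
preset adds a cos(tilt) vertical foreshortening. Defaults are the study
conditions the analysis emulates: 11 subjects, cadence 106.44 (SD 8.1)
steps/min, step time ≈ 0.57 s with CV 0.06, step width 0.09 m, hip width
0.30 m, 2–3 front and 1–2 back bouts of 11–15 steps per subject, 30 fps
video against a 100 Hz reference, cameras at 1.11 m and 2.05 m. Per-step
foot-placement jitter (SD 0.025 m) puts the step-width CV near 0.4, the
range observed for older adults walking at self-selected speed.

Corruption emulates tracker failure modes, all deterministic under a seed
and logged for scoring: i.i.d. Gaussian pixel noise (default SD 3 px, with a
per-tracker multiplier — one tracker is noisier so pairwise agreement is not
degenerate), per-frame-joint confidence dropouts drawn below every tracker's
threshold, and per-frame left/right exchanges of one random lower-limb pair.
The noise can be restricted to the lateral image axis
(`pixel_noise_axes="x"`): that is the construction used for the
temporal-vs-spatial validity property, where the event-timing channel (the
vertical ankle trajectory) stays clean while the spatial variables absorb
the noise. With noise on both axes, strike-time jitter honestly drags
individual-step step-time correlations down to the 0.4–0.7 range while
cadence stays near 1 — the same ordering, but the temporal correlations no
longer sit above 0.95.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: autocorrelated tracker jitter, occlusion of the
leading leg in back views, motion blur, out-of-plane (sagittal) motion,
camera distortion, and real anthropometric variation in limb proportions.
Parameter-recovery results on clean synthetic walks are a correctness check
of the pipeline, not an accuracy claim for real video.

## Problem sizes and numerical choices

Simulated cohorts use 11 subjects with 2–3 front and 1–2 back bouts of
11–15 steps (≈ 350–400 front-view steps), matching the emulated study scale;
property checks over cohorts use 10–30 seeds, chosen as the package's own
test scale. Filters require n > 3×(order+1) samples; degenerate statistics
raise typed errors (zero-variance correlation, zero-mean CV, fewer than two
strikes for cadence) rather than returning NaN silently, except in batch
summaries where a NaN cell plus a warning keeps the run alive. Ties in
person selection and event sorting are broken deterministically. All
randomness flows through `numpy.random.default_rng` seeds; reruns are
byte-identical.

## Known limitations

* Step width from the ankle lateral coordinate (COCO has no foot landmark
  common to all three trackers) differs from a foot-centre definition by a
  roughly constant offset per subject.
* The averaging effect (per-participant means correlating better than pooled
  individual steps) is driven by per-step measurement noise; for variables
  the pipeline recovers nearly perfectly (cadence, and the CVs on clean
  timing) both methods saturate and their difference is ~0.
* eMOS in hip-width units is not directly comparable to metre-scale
  reference values; only correlations and tracker-pair agreement are
  meaningful across that unit boundary.
* The alignment assumes a known (or zero) clock offset between systems; it
  does not estimate one.
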