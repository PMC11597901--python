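# Methods

This note documents the models, conventions and design choices behind the
package: how the synthetic study emulates a markerless-vs-reference gait
validation experiment, how the kinematic and statistical estimators are
defined, and what the passing checks do and do not demonstrate about real
data.

## The measurement problem

Markerless motion capture (MMC) estimates human pose from video (here, a
COCO-17 keypoint detector combined with depth sensing across three
cameras) and computes joint angles directly from the estimated 3-D joint
centers. Validating such a system against marker-based optoelectronic
motion capture requires two families of evidence:

* **accuracy** — agreement with the reference system within a session:
  waveform RMSE and Lin's concordance correlation (CCC) over the full gait
  cycle, plus Bland–Altman bias/limits of agreement and Pearson r on the
  discrete parameters (maximum, minimum, range of motion);
* **test–retest reliability** — stability across sessions a week apart:
  ICC(2,1), the standard error of measurement (SEM) and the minimal
  detectable change (MDC) on discrete parameters, plus waveform RMSE/CCC
  between sessions.

The real studies of this kind rest on human recordings that are not
publicly deposited; this package therefore pairs the full analysis chain
with a synthetic data generator whose ground truth is known exactly, so
that every stage can be validated end to end.

## Coordinate and angle conventions

World frame: X along the walking direction, Y mediolateral (left
positive), Z vertical. Units are metres, seconds, degrees, newtons.

Flexion angles are computed by the vector method. For a joint with vertex
`v` and adjacent points `a`, `b`, both limb vectors are projected onto the
sagittal plane (the plane orthogonal to the mediolateral axis), and

```
flexion = sign · (180° − ∠(a − v, b − v))
```

so a fully extended (collinear) segment pair reads 0°. The sign is the
sign of the cross-product component along the sagittal normal; the normal
is oriented per joint and side (+Y for the right hip, −Y for the right
knee; both flipped on the left) so that anatomical flexion is positive.
Hip flexion uses (shoulder, hip, knee) with the same-side shoulder; knee
flexion uses (hip, knee, ankle). With one keypoint per foot, ankle angles
are not computable.

The angle magnitude is invariant under any global rigid transform of the
world, and under reflection through the sagittal plane; both properties
are tested.

## Synthetic gait model

Joint-angle waveforms are truncated Fourier series in gait phase
φ ∈ [0, 1) (H = 4 harmonics): smooth, periodic, differentiable, and exactly
recoverable. The default shapes follow normal sagittal gait: hip flexion
≈ +28° peaking in late swing, extension ≈ −12° in late stance; knee
flexion with a stance bump (≈ 24°) and a swing peak (≈ 60°). Two
properties of the knee curve are deliberate design constraints rather than
aesthetics:

* **the global minimum sits at φ = 0** (terminal-swing full extension at
  heel strike), which is what makes segmentation by the knee-flexion
  minimum commensurate with segmentation by GRF heel strikes;
* **the midstance valley stays ≈ 7° above the terminal-swing minimum**,
  so the global-minimum event detector cannot lock onto the wrong valley
  under participant-level waveform perturbation or observation noise; and
  the bump widths are broad enough that a 30 Hz sampling grid captures the
  peaks to ≈ 0.1–0.2° in expectation (the waveform must be representable
  at the markerless frame rate for noise-free self-consistency to hold to
  the 0.5° contract).

Cycle duration decreases monotonically with treadmill speed
(T = 0.90 + 0.25/v seconds, ≈ 1.26/1.15/1.09 s at 0.7/1.0/1.3 m/s) and the
stance fraction is ≈ 0.62 at 1.0 m/s, slightly decreasing with speed.

Forward kinematics places the 17 COCO keypoints from a sagittal-plane
chain: vertical trunk (hip→shoulder), thigh rotated forward by the hip
angle, shank rotated back from the thigh by the knee angle; the left side
runs half a cycle out of phase; the pelvis carries a small vertical and
lateral oscillation; head and arm keypoints are fixed offsets plus a small
arm swing. The defining contract, tested to 1e-6°, is that re-deriving
hip/knee flexion from the generated keypoints by the vector method returns
the model waveform exactly.

Anthropometry uses standard segment-fraction tables (trunk 0.288, thigh
0.245, shank 0.246 of stature; stature ~ N(1.75, 0.10) m truncated to
[1.45, 2.05]).

## Observation models

**Markerless chain (3 cameras at 30 Hz, front/back/right side).** Per
camera the true poses are linearly resampled to 30 Hz, then corrupted by

* constant per-keypoint joint-center offsets (systematic mislocalization
  by the pose estimator; also how a constant angle bias is injected — a
  shoulder shift of trunk_length·tan(θ) biases hip flexion by exactly θ
  because the generated trunk is vertical);
* a depth-surface bias pulling every point toward the observing camera
  along the camera→point ray (depth sensors report the nearest body
  surface, not the internal joint center);
* isotropic Gaussian noise (default SD 10 mm — a plausible scale for
  pose-plus-depth keypoints; no published measurement fixes it);
* random dropout (default 2 %) encoded as absent positions with
  confidence 0.

Observations are emitted in each camera's own frame; the analysis chain
transforms them back with the extrinsics (p_world = R·p_cam + t).

**Reference chain.** Angle truth resampled to 100 Hz plus i.i.d. Gaussian
noise (default SD 0.3°), standing in for a marker-based system with its
own (small) measurement error. Vertical GRF at 1000 Hz is zero in swing
and a double-bump profile in stance whose rising 0→positive crossing
coincides exactly with the ground-truth heel strike; a sharp heel-strike
transient makes the onset steep so threshold detection is accurate to
≈ 1 ms.

**Study design.** 15 participants × 2 sessions × 3 speeds (0.7/1.0/1.3
m/s), 60 s per trial (desk-scale stand-in for a 3-minute recording;
configurable). Each participant draws anthropometry and a gait-model
perturbation (amplitude scale SD 0.06, baseline SD 2°, harmonic SD 0.8°,
cycle-duration SD 5 %). Session 2 re-uses the participant's parameters
plus a small waveform perturbation (harmonic SD 0.2°, baseline SD 0.4° —
≲ 1° RMS waveform change) and fresh per-keypoint localization offsets
(SD 3 mm), giving test–retest structure whose reliability lands in the
good-to-excellent band. All randomness flows from a single seed.

## Analysis chain

1. **Fusion.** Per keypoint per frame, cameras farther than 0.15 m from
   the per-keypoint median are excluded, the survivors combined by
   confidence-weighted mean (unweighted if all surviving confidences are
   zero). Fusing a single camera is the identity. The merging rule is a
   design choice — robust to one bad camera, degrades gracefully to plain
   averaging.
2. **Filtering.** 4th-order zero-phase (forward–backward) Butterworth,
   6 Hz cutoff, applied to the fused keypoint trajectories, not to the
   angles. Interior gaps of ≤ 3 frames are linearly interpolated first;
   longer gaps or > 10 % missingness of a required keypoint fail loudly.
   Waveform segments within ~0.5 s of the trial edges are discarded before
   event analysis (filter edge transients).
3. **Events.** Markerless cycles start at local minima of knee flexion:
   troughs separated by ≥ 0.6 × the expected cycle (estimated by the
   strongest autocorrelation peak when not supplied), depth-gated against
   the median trough (median + max(2°, 5·MAD)) so a partial leading cycle
   cannot surface the midstance valley, and refined to sub-sample
   precision by a parabolic fit through the trough — at 30 Hz the raw grid
   alone would quantize every cycle start by ±17 ms. Reference cycles
   start at heel strikes: upward 20 N crossings of the vertical GRF with a
   0.3 s refractory period and linear-interpolation refinement.
4. **Normalization.** Each inter-event interval is linearly resampled to
   101 points spanning 0–100 % of the cycle (the field's convention);
   partial cycles are discarded. Discrete parameters are per-cycle extrema
   averaged across cycles (average-of-extrema), with the
   extrema-of-the-mean-curve variant available; ROM = max − min exactly.
5. **Agreement statistics.** All covariances use n − 1 denominators.
   - Waveform RMSE per participant over the 101-point grid between the
     two systems' (or two sessions') mean cycles; reported as mean ± SD
     across participants. The CCC over waveforms is computed on the pooled
     point pairs of all participants.
   - CCC = 2s_xy / (s_x² + s_y² + (x̄ − ȳ)²), CI via the Fisher
     z-transform with Lin's asymptotic standard error. |CCC| ≤ |r| always.
   - Bland–Altman: d = A − B, bias = mean(d), LoA = bias ± 1.96·SD(d);
     the bias is by construction the midpoint of the LoA.
   - ICC(2,1): two-way random effects, absolute agreement, single
     measures, from the ANOVA mean squares
     (MS_R − MS_E)/(MS_R + (k−1)MS_E + k(MS_C − MS_E)/n), CI by the
     F-based method; cross-checked in the tests against an explicit ANOVA
     decomposition and against an independent implementation.
   - SEM = SD·√(1 − ICC) with the SD pooled over both sessions'
     measurements. MDC: the default factor is 1.96/√2 (≈ 1.386), the
     arithmetic several published gait-reliability tables follow; the
     conventional MDC95 = 1.96·√2·SEM is selectable. Neither convention is
     asserted as "correct"; the default simply reproduces the table
     arithmetic this pipeline is built to emit.
   - Offset correction: per participant-session, the mean difference
     between the markerless and reference mean cycles over the phase grid
     is subtracted from the markerless waveform (and from its max/min).
     The residual mean is zero exactly and every ROM statistic is
     unchanged to machine precision; subtracting the mean difference is
     also the RMSE-optimal constant shift, so corrected waveform RMSE can
     never exceed uncorrected.
   - Degenerate inputs (zero variance) raise explicit errors instead of
     returning NaN.
6. **Reports.** Reliability uses both sessions of the markerless chain;
   accuracy pairs markerless and reference summaries per
   participant-session (both sessions pooled by default, configurable),
   each joint × speed a row, with the interpretation bands attached
   (Pearson: 0.9–1.0 "very high" …; CCC: 0.95–0.99 "substantial" …;
   ICC: 0.75–0.9 "good", 0.9–1.0 "excellent").

## Experiment design notes

* The **bias-recovery experiment** (constant +6° hip offset via a shoulder
  joint-center shift) uses affine-only participant variation (amplitude/
  baseline/cycle-duration, zero harmonic-shape noise) and zero keypoint
  noise: affine waveform changes do not move extrema phases, so the two
  systems' cycle origins stay aligned and the experiment isolates the
  offset mechanism from the segmentation-convention mismatch, which is a
  separate, realistic effect present in the default study.
* **Problem sizes** are chosen for desk-scale runs: 60 s trials for the
  full study (≈ 45–55 cycles each), 20–30 s for targeted experiments; a
  full 90-trial study simulates and analyses in well under a minute.

## What the synthetic study does and does not show

The generator reproduces the *structure* of the experiment — sampling
rates, camera geometry, test–retest design, joint-center and depth-bias
error mechanisms, peak undersampling at 30 Hz — with known ground truth.
It does not model soft-tissue artifact, pose-estimator failure modes
(identity switches, systematic phase-dependent mislabeling), non-sagittal
kinematics, treadmill drift, or inverse-kinematics constraints on the
reference side; reference angles are truth plus white noise rather than
the output of a skeletal model. Passing checks therefore demonstrate the
correctness and internal consistency of the pipeline and its statistics
under the stated error model — not the field accuracy of any particular
hardware.

## Known limitations

* Fusion assumes cameras share a common frame clock (timestamps aligned
  within half a frame); no temporal registration is performed.
* The knee-minimum event convention differs from the heel-strike
  convention by the (small) phase offset of the knee minimum; with real,
  less stereotyped waveforms this mismatch can grow and contributes to
  inter-system waveform RMSE exactly as it does for real systems.
* Only the right side is analysed; the left side exists in the generator
  for geometric completeness.
* TRC and delimited text are the only mocap exchange formats; binary C3D
  is out of scope.
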