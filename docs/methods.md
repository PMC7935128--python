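# Methods

## Data model and conventions

A trial is one walk of one mouse.  Sagittal-plane markers (right hindlimb:
iliac crest, hip, knee, ankle, 5th metatarsal head) are (x, y) in mm with
x the direction of travel (anterior positive) and y vertical up;
transverse-plane hindpaw tracks are (x, y) with y lateral, right positive.
Units are millimetres internally; `TrialConfig.unit_scale` converts tracker
units on read.  The frame rate is required configuration — tracker exports
rarely store it reliably, and nothing downstream can infer it.  Missing
samples are NaN throughout; they are never silently zero-filled.

On disk a trial is a wide CSV (`<marker>_x`, `<marker>_y`, `rpaw_*`,
`lpaw_*`, one row per frame, `NA` missing token) with `# key: value` header
comments for metadata.  Values are written with 12 significant digits, so a
write/read round trip reproduces coordinates to better than 1e-9 mm at
laboratory magnitudes.

## Joint angles

The interior angle at each joint is the law-of-cosines angle of its marker
triplet — hip: (iliac crest, hip, knee); knee: (hip, knee, ankle); ankle:
(knee, ankle, metatarsal).  The cosine argument is clamped to [−1, 1] to
absorb floating-point overshoot on collinear triples; a genuinely
zero-length segment (< 1e-9 mm) is a geometry error naming the frame.  All
angles live in [0, 180] degrees.  Because the interior angle is unsigned,
the mapping to clinical terms is a documented convention, not an
assumption: ankle **dorsiflexion** = decreasing interior angle,
**plantarflexion** = increasing.

Angle traces are normalized per gait cycle onto a 101-point 0–100% grid by
linear interpolation (0% = opening footstrike, 100% = closing footstrike),
the standard convention of quantitative gait analysis.  Normalization is
idempotent on an already-gridded curve.  No smoothing is applied by
default; an optional odd-window moving average (`smooth_window`) exists for
noisy recordings and must be requested explicitly so the choice is visible.
For recordings with ~0.3–0.5 mm marker jitter a 3-frame window is the
recommended setting: wider windows visibly clip the sharp extrema of the
hip and knee waveforms (measured attenuation >2° at window 5), while window
3 keeps the mean extrema bias of every joint near or below 1°.

## Contact events and cycles

Marker recordings carry no force plate signal, so ground contact is
inferred from the toe trajectory in two stages:

1. **Coarse stance mask.**  A frame is stance when the smoothed forward
   speed is below `speed_threshold` (default 15 mm/s) *and* the toe sits
   below `height_threshold` (default 3 mm) above the ground line, estimated
   per trial as the 5th percentile of toe height.  Speed comes from a
   Savitzky–Golay first derivative whose window spans a fixed time
   (default 0.11 s) rather than a fixed frame count, so the estimator's
   noise does not grow with frame rate.  Gaps of up to `merge_gap` frames
   (default 2) inside a run are closed; runs shorter than
   `min_stance_frames` (default 3) are discarded.
2. **Boundary refinement.**  Smoothing blurs contact boundaries by about
   half the window, so each run entry/exit is sharpened with a raw
   per-frame displacement test: a footstrike is the first frame (within a
   window around the coarse boundary) whose next two displacements both
   fall below a threshold, a toe-off the first frame with a sustained
   displacement above it.  The threshold adapts to the data:
   max(0.3 mm, 3 × the MAD-estimated stance jitter), so it is sharp on
   clean data and conservative on noisy data.

Events are integer frame indices; sub-frame timing is deliberately not
estimated, because every downstream quantity is validated at frame-level
tolerances.  On noise-free synthetic gaits detected events sit within one
frame of the construction's contact onsets (the onset of a smooth,
zero-velocity touch-down is ambiguous by one frame at any threshold).

Cycles are strike-to-strike intervals, each carrying its interior toe-off;
consecutive cycles share boundary frames.  Steady-state analysis takes the
**middle two cycles**: for `n` cycles, 0-based indices `(n−2)//2` and
`(n−2)//2 + 1` — for odd `n` the earlier of the two central pairs, a
deterministic tie-break.

For the left hindpaw only a transverse track (no height) exists; detection
then runs on forward position alone with the height gate skipped.

## Scalar parameters

Per joint: minimum, maximum and ROM = max − min over the normalized cycle.
Stride length is the full planar distance between the paw's positions at
the opening and closing footstrikes (it reduces to the forward shift when
lateral drift is zero — "shift", not "forward component", is the measured
quantity).  Step width is the mean absolute lateral separation between the
right-paw stance centroid and the nearest-in-time left-paw stance centroid,
averaged over the analyzed cycles.  Per-trial values average the two
steady-state cycles, treated as replicate strides of one walk; the right
(instrumented) hindpaw is the default stride paw.

## Statistics

Group contrasts use the two-sided pooled-variance Student's t-test
(df = n₁ + n₂ − 2); Welch's variant is available behind `equal_var=False`.
Values are reported as mean ± SEM.  Zero pooled variance with equal means
yields t = 0, p = 1; with unequal means it is an error rather than an
infinite statistic.  Significance tiers 0.05/0.01/0.001 render as
\*/\*\*/\*\*\* for group contrasts and #/##/### for within-group timepoint
contrasts.  Timepoint comparisons are unpaired: whether repeated measures
on the same animals should be paired is a design question the package does
not presume to answer; a paired analysis can be built from the parameter
table directly.

Curve comparisons run a t-test at each of the 101 grid points and report
the significance mask.  No multiplicity correction is applied by default —
matching the per-point star convention of gait figures — and a
Benjamini–Hochberg option exists and labels its output.  Pointwise masks
should be read as descriptive localization, not family-wise inference.

## Synthetic gait generator

The generator is trajectory-first: stance timing, stride and width are
exact by construction, so every stage has a sharp oracle.

* Pelvis: the hip advances at constant speed, `hip_height` 26 mm with a
  0.8 mm vertical oscillation (two per stride); the iliac crest rides at a
  fixed (6, 10) mm anterior-dorsal offset.
* Toe: stationary on the ground for `duty_factor` (0.6) of each cycle, then
  a cosine-eased forward swing (zero velocity at lift-off and touch-down)
  with a `swing_clearance` (6 mm) arc of zero end slope.
* Ankle: placed from the toe through the 10 mm foot segment with a
  two-harmonic foot-pitch waveform (mean 115°, amplitudes 22°/6°), tuned so
  peak plantarflexion falls near push-off.
* Knee: two-segment inverse kinematics between hip and ankle (thigh 17 mm,
  shank 18 mm), fixed to the anatomical knee-forward branch; segment-length
  residuals are below 1e-9 mm and unreachable poses raise an error naming
  the frame.
* Left hindpaw: mirrors the right at lateral offset `step_width` with a 50%
  phase shift.
* Noise: i.i.d. Gaussian per marker coordinate, added after truth capture.

Defaults: 6 cycles of 60 frames at 240 fps (a 4 Hz stride under a
high-speed camera), stride 60 mm, step width 15 mm — a medium-paced walk of
an adult mouse.  Validation analyses that need more strides or specific
noise levels say so explicitly (20 cycles for spatial recovery; σ = 0.3–0.5
mm marker jitter); event-timing checks use a coarser 25 frames/cycle at
100 fps configuration where contact onsets are steep.

True joint angles are computed from the noise-free markers with an
atan2-based vector formula — an independent code path from the pipeline's
law-of-cosines route — so their agreement (required < 1e-6°, measured
~1e-13°) is a genuine cross-check.  True extrema come from a dense
(2000-point) phase grid of the same construction.

**Phenotype presets.**  `control` is the default configuration.
`affected` applies documented deltas: step width ×1.3, stride ×1.15,
foot-pitch amplitude ×1.6 and mean +7° (both age-scaled by 0.5 at 6 weeks
rising to 1.0 at 14), and ×1.5 pelvis oscillation.  At the terminal age
this yields a lower ankle interior-angle minimum (more dorsiflexed
terminal stance), a slightly lower maximum (less plantarflexed swing),
greater ankle ROM, and an ankle phenotype that progresses with age.  These
numbers are **invented calibrations reproducing reported qualitative
directions** for a demyelinating-neuropathy model; no quantitative angle
measurements stand behind them, and they should not be read as biology.
The magnitudes were fixed by design analysis: with the cohort model below,
the ankle-ROM effect size at n = 5 per group is Cohen's d ≈ 2.5–3, i.e.
reliably detectable at the small group sizes typical of mouse studies.

**Cohorts.**  Between-mouse variation multiplies stride, width, ankle
amplitude and swing clearance by independent lognormals (CV 5%) and jitters
the foot-pitch mean by N(0, 1.5°); hip height uses a smaller 2% CV —
standing posture is far more uniform across age-matched inbred littermates
than gait style, and pelvis height couples strongly into every joint angle
through the limb geometry.  In longitudinal studies each mouse keeps its
perturbation across ages (the same animals are followed); each recording
gets fresh marker noise.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: tracking outliers and marker occlusion
(noise is i.i.d. Gaussian, not heavy-tailed or temporally correlated),
stride-to-stride timing variability within a trial (cycles are exactly
periodic), speed drift or acceleration, out-of-plane limb motion, and paw
deformation during push-off.  Recovery tolerances quoted here are
best-case; real recordings will sit above them.

## Numerical choices

* arccos argument clamped to [−1, 1]; 1e-9 mm minimum segment length.
* 101-point grid, linear interpolation, `np.interp` on frame indices.
* SD of a single curve is 0 by convention and flagged (`single_curve`).
* Sample SD everywhere (ddof = 1); SEM = SD/√n.
* Event refinement threshold: max(0.3 mm, 3 × MAD jitter); the 1.5× factor
  on the two-frame displacement test suppresses isolated noise spikes.
* Seeds: every stochastic routine takes an explicit seed or Generator;
  identical config + seed reproduces trials bit-for-bit.

## Known limitations

* Sagittal angles only; no frontal-plane or 3-D kinematics.
* Contact detection is heuristic (speed + height gating); it has no access
  to force data and inherits the ±1-frame ambiguity of smooth touch-downs.
* Temporal parameters (cadence, swing velocity) and interlimb coordination
  indices are out of scope.
* The statistics module implements the t-test family only; repeated
  measures across ages are treated as unpaired unless the user pairs them.
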