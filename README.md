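# mousegait

Marker-based gait analysis for mouse models of peripheral neuropathy.

Motor phenotyping of mouse disease models — for instance Trembler-J, a
*Pmp22* point-mutant model of Charcot–Marie–Tooth disease type 1 — needs
readouts that track disease progression better than rotarod time or nerve
conduction, which bottom out early.  Kinematic gait parameters fill that
gap: commercial runway systems film a walking mouse from the side and from
below, and markers on the **iliac crest, hip, knee, ankle and 5th metatarsal
head** of the right hindlimb are tracked frame by frame.  `mousegait` turns
those marker tracks into the standard gait parameters and group statistics:

* **Joint angles** — the interior angle at the hip (iliac crest–hip–knee),
  knee (hip–knee–ankle) and ankle (knee–ankle–metatarsal) is computed per
  frame with the law of cosines, `cos θ = (a² + b² − c²) / 2ab`, from the
  Euclidean distances between the three markers.  Ankle dorsiflexion
  decreases the interior angle; plantarflexion increases it.
* **Gait cycles** — a cycle runs from one ground strike of the right
  hindpaw to its next strike.  Contact events are detected from the toe
  trajectory (low forward speed and low height above a per-trial ground
  line, with displacement-based boundary refinement); toe-off splits each
  cycle into stance and swing.  The **middle two cycles** of a walk are
  analyzed, excluding acceleration and deceleration.
* **Scalar parameters** — per-joint minimum, maximum and range of motion
  (ROM = max − min) over the cycle, normalized to a 101-point 0–100% grid;
  stride length (hindpaw shift between successive strikes) and step width
  (lateral hindpaw separation during stance) from the transverse plane.
* **Statistics** — two-sided pooled-variance Student's t-tests per
  parameter and timepoint (mean ± SEM, tiers \*/\*\*/\*\*\* at
  0.05/0.01/0.001, `#`-style for within-group timepoint contrasts), plus
  pointwise t-tests along the normalized angle curves.

Because public marker-level recordings of this kind are scarce, the package
ships a **synthetic gait generator**: a planar hindlimb chain driven by an
explicit toe trajectory (stationary stance, smooth swing arc), a
phase-dependent foot pitch, and two-segment inverse kinematics, with exact
ground-truth angles, events, stride and width.  Control-like and
affected-like (Trembler-J-like) presets encode the reported phenotype
directions — wider step width, longer stride, more dorsiflexed ankle with
greater ankle ROM, progressing with age.  Every pipeline stage is validated
against this ground truth.

## Worked example

```python
from mousegait import (make_preset, generate_trial, analyze_trial,
                       run_study, compare_groups)

# one noisy recording of a control-like mouse, full pipeline
cfg = make_preset("control", age_weeks=14, noise_sd=0.3, seed=1)
trial, truth = generate_trial(cfg)
ps = analyze_trial(trial, smooth_window=3)

# a 5-vs-5 study at 14 weeks, per-parameter t-tests
table = run_study(seed=42, ages=(14,))
res = compare_groups(table[table.group == "control"],
                     table[table.group == "affected"])
```

Formatted, the resulting `ParameterSet` and comparisons read:

```
subject sim (control, 14 wk), 2 steady-state cycles
  hip  : min   46.2  max  157.8  ROM 111.6 deg
  knee : min   31.7  max   94.6  ROM  62.9 deg
  ankle: min   71.2  max  139.9  ROM  68.7 deg
  stride length  60.8 mm (truth 60.0)
  step width     15.1 mm (truth 15.0)

ankle_min    : control  71.90+-1.38  affected  57.24+-1.87  t=  6.31 p=0.0002 ***
ankle_rom    : control  67.52+-1.44  affected  79.53+-1.80  t= -5.21 p=0.0008 ***
stride_length: control  60.25+-0.54  affected  68.71+-1.21  t= -6.40 p=0.0002 ***
step_width   : control  15.67+-0.32  affected  19.24+-0.67  t= -4.82 p=0.0013 **
```

The single-trial block shows the pipeline recovering the generator's truth
(60 mm stride, 15 mm width) from noisy markers; the study block shows the
affected phenotype — lower ankle minimum (more dorsiflexion), greater ankle
ROM, longer stride, wider base of support — flagged at n = 5 per group.

A command-line interface covers the same workflow on CSV files:

```bash
mousegait simulate --preset affected --age-weeks 14 --n-mice 5 --out trials/aff
mousegait analyze trials/aff/*.csv --out aff_params.csv
mousegait compare ctrl_params.csv aff_params.csv --out results.csv
mousegait report ctrl_params.csv aff_params.csv --out-dir report/
```

## Layout

```
src/mousegait/
  io_markers.py      trial CSV dialect, TrialRecording / TrialConfig
  kinematics.py      law-of-cosines angles, 101-point cycle normalization
  events.py          footstrike/toe-off detection, cycles, steady state
  parameters.py      ROM, stride length, step width, per-trial summaries
  stats_report.py    t-tests, curve comparisons, results CSV + figures
  synthetic_data.py  ground-truth gait generator and phenotype presets
  study.py           simulated longitudinal cohorts, end to end
  cli.py             simulate / analyze / compare / report
```

See `docs/methods.md` for the model, conventions, parameter defaults and
known limitations.
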