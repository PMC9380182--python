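# actionselect

A tested behavioural-analysis pipeline for an externally cued **motor action
selection** task used in stroke upper-extremity research, together with a
synthetic-data generator that makes the whole measurement chain verifiable
against known ground truth.

## The problem

In the task, a participant moves a spring-centered joystick (maximum
excursion 20° of deflection) with the more-impaired hand under two
conditions:

- **Select** — an abstract rule maps four visual cues to a direction
  (small square or large circle → left; large square or small circle →
  right);
- **Execute** — the same cues appear, but the movement direction is fixed
  (counterbalanced across participants).

Cues last 2 s with a 2.0–3.5 s jittered inter-trial interval; practice runs
over four days (72 analysis trials per condition on Day 1, 96 on Days 2–4,
in alternating 24-trial blocks). Joystick position (x, y) is sampled at
60 Hz.

Per trial, the pipeline derives velocity from position (optionally low-pass
filtered, then central differences) and applies rule-based event detection:

- **onset** — first of two consecutive samples with speed > 5°/s;
- **offset** — first post-peak sample below a peak-dependent floor
  (10°/s if peak < 30; 25°/s for peaks 30–100; 40°/s above 100) where the
  x-velocity reverses or the speed change is < 5°/s.

From these: reaction time `RT = t_onset − t_cue` (accurate trials only),
movement time, movement amplitude, peak velocity, and direction accuracy
(sign of x at the time of peak velocity). The primary planning statistic is
the **RT cost**,

```
RT cost = mean RT(Select) − mean RT(Execute)      per subject × day,
```

which isolates the action-selection (choice) component of planning time from
general slowing. The statistical layer provides the within-subject
(repeated-measures) ANOVA with condition × day factors and effect-specific
error terms, exact/approximate Wilcoxon signed-rank tests, Pearson
correlations, Welch/pooled t tests for lesion-side (LBD vs RBD) subgroups,
and a 2.5-SD outlier sensitivity rerun. A cohort module ingests the
16-participant clinical table and computes the corticospinal-tract
fractional-anisotropy ratio, `mean FA(lesioned) / mean FA(non-lesioned)`
over peduncle voxels with FA > 0.2.

## Worked example

```bash
python analysis/01_design_schedules.py    # counterbalanced 4-day schedules
python analysis/02_simulate_cohort.py     # 16-subject synthetic cohort -> scratch/
python analysis/03_detect_and_summarize.py
python analysis/04_statistics.py
python analysis/05_validate_detection.py
python analysis/06_figures.py
```

With the default seed, step 03 prints (excerpt):

```
reaction time (s):
  Execute  Day 1: 0.480 +- 0.172; Day 2: 0.473 +- 0.172; Day 3: 0.478 +- 0.170; Day 4: 0.477 +- 0.164
  Select   Day 1: 1.148 +- 0.314; Day 2: 1.043 +- 0.251; Day 3: 0.987 +- 0.233; Day 4: 0.879 +- 0.188
RT cost, Select - Execute (s):
  Day 1: 0.669 +- 0.227; Day 2: 0.570 +- 0.165; Day 3: 0.510 +- 0.118; Day 4: 0.402 +- 0.078
QC: 128 omissions, 0 anticipations, 0 truncated offsets across 11904 trials
```

Reading: Select responses start ~0.7 s later than Execute on Day 1 (the
action-selection cost), and four days of practice cut that cost by ~0.27 s
while Execute RT — and all movement-execution measures (movement time,
amplitude, peak velocity) — stay flat. Step 04 confirms this statistically
(condition and day effects on RT, day effect on RT cost at p < .001;
no effects on execution measures) and step 05 shows the detector recovers
latent onsets within one 60-Hz sample on 100% of trials at the default
0.05° position noise.

The same functionality is available as a CLI
(`actionselect simulate|analyze|validate|cohort|report`) and as library
calls (`actionselect.pipeline.run_simulate` / `run_analyze`).

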