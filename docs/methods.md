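# Methods

This note documents the models, rules, parameters and numerical choices
behind the package, and what the synthetic validation studies do and do not
demonstrate.

## Task and schedule model

Two conditions share four visual cues (square/circle × small/large; the
large cue is drawn at twice the small cue's size, recorded as metadata
only). Select maps cues to directions by the abstract rule (small square,
large circle → left; large square, small circle → right; a `mirrored`
variant flips both). Execute prescribes one fixed direction per participant.
Cue duration is 2 s; the inter-trial interval is drawn **continuously
uniform on [2.0, 3.5] s** (the jitter distribution is otherwise
unspecified; a uniform draw is the conventional choice). Cue order within a
24-trial block is **stratified** — each of the four cues appears n/4 times,
then the order is permuted — so Select direction frequencies stay 50/50 per
block.

A laboratory session holds alternating-condition blocks: Day 1 has a
familiarization Select block (generated, flagged, excluded from analysis)
followed by 3 blocks per condition; Days 2–4 have 4 blocks per condition.
The paradigm's description of later days is internally inconsistent (10
blocks of 24 trials per day cannot total 96 trials per condition); we honor
the explicitly stated per-condition totals — 72 on Day 1, 96 on Days 2–4 —
because every downstream dataset size derives from them, and read the block
count as the slip.

The imaging-run generator produces the block design: two 24-s movement
epochs of 5 trials each alternating with 24-s rest epochs, separated by 8-s
fixations. The printed run length (2 min 35 s) is not an integer
combination of 24-s and 8-s epochs, so the run opens with a **27-s lead-in
fixation** (instruction/steady-state period); all separating fixations are
exactly 8 s and the total is 155 s. Five 2-s cues with four jittered ITIs
occupy at most 10 + 4×3.5 = 24 s, so movement epochs always fit.

Counterbalancing of (first condition × Execute direction) cycles
deterministically through the four combinations in enrollment order; both
factors stay balanced to within one subject at any cohort size.

## Trajectory generator

One trial spans cue onset to the next trial's onset at 60 Hz. After a
latent reaction time drawn **lognormal, parametrised by its mean** (shape
`rt_sigma = 0.25`; positive support and right skew are the standard choice
for choice RT), the stick moves along x as a **minimum-jerk profile**
x(t) = D(10τ³ − 15τ⁴ + 6τ⁵) with peak speed 1.875·D/T, holds 0.2 s at the
target, and returns to center as a **critically damped spring**
x(t) = A(1 + t/τ)e^(−t/τ) with τ = 150 ms. The y axis carries measurement
noise only (the task is purely left/right). Independent Gaussian noise
(default SD 0.05°) is added to both axes. Error trials flip the movement
sign; omissions produce no movement; anticipations draw RT uniform on
[0, 0.1) s (default probability 0).

The latent RT is **realised on the 60-Hz sample grid** (rounded to the
nearest sample) and the grid-aligned onset/offset are stored as ground
truth. Recovery tolerances for a sampled detector are statements in whole
samples; only grid-aligned latent events make "onset error ≤ 1 sample" a
well-defined target for arbitrary movement durations. Consequence: on
noiseless trials the detector's 5°/s crossing sits exactly one sample after
the latent onset, so the median detected-RT error is one sample (16.7 ms)
by construction.

Trajectory defaults, chosen once as realistic for a brisk joystick flick by
participants with mild-to-moderate impairment: movement duration
**T = 0.25 s** (15 samples), amplitude target **15°** of the 20° maximum
excursion (between-subject SD 2°, clipped to [5°, 20°]), giving peak speeds
near 112°/s — inside the detector's highest offset bin, with the spring
return (peak return speed A/τe ≈ 37°/s) safely below the 40°/s floor.

## Cohort model

Population parameters default to the study conditions: Execute trial-RT
mean 0.542 s (between-subject SD 0.207, flat across days), Execute accuracy
98.2% (SD 3.3); Select RT = Execute + RT cost; Select accuracy 87.3%
(SD 13.6) on Day 1 improving linearly to 95% (SD 5) on Day 4; omission
probability 1%.

Individual RT-cost practice curves follow a **growth-curve model**:

cost(subject, day) = μ(day) + b + s·(day−1)/3 + e(day),

with population means μ declining linearly 0.552 → 0.353 s, a subject
baseline offset b, a subject practice slope s, and a day-level residual e
(SD 0.03 s). The joint distribution of (b, s) is moment-matched to three
cohort quantities — Day-1 SD 0.238 s, Day-4 SD 0.099 s, Day-1/Day-4
correlation .368 — which forces a strong negative baseline–slope
correlation (high starters improve most, the usual practice pattern) and
yields smooth individual curves. An earlier parametrization that drew
per-day deviations independently reproduced the same two SDs and the
correlation but implied erratic day-to-day jumps within subjects; the
growth-curve model replaces it as the more realistic emulation of practice
data. Infeasible moment combinations (negative slope variance, |ρ| > 1) are
rejected at configuration time.

Determinism: a master seed spawns one stream per subject (parameters) and
per subject-day (schedule, trajectories), so any subset regenerates
bytewise identically.

## Event detection and measures

Velocity is computed by central finite differences (one-sided at the
endpoints); speed is the resultant √(vx² + vy²). Detection runs on
resultant speed; left/right lives on signed x.

- Onset: earliest sample i with speed[i] > 5 and speed[i+1] > 5 (strict
  inequalities; the onset timestamp is the first sample of the pair). The
  alternative onset clause (velocity change < 1°/s for two consecutive
  samples) would fire at rest as printed; it is implemented only as a
  documented, off-by-default variant.
- Offset: earliest post-peak sample below the peak-dependent floor
  (10 / 25 / 40°/s; the 30 and 100 edges are assigned to the middle bin)
  with an x-velocity sign reversal or |Δspeed| < 5°/s. If the rule never
  fires the last sample is used and the trial flagged truncated.
- Measures: RT = onset − cue onset (accurate trials only enter RT
  summaries); movement time = offset − onset; amplitude = onset→offset
  Euclidean displacement (a path-length variant is available behind a
  flag, since "total amplitude" is ambiguous); peak velocity; direction at
  peak = sign of x. Outcomes: omission (no onset), anticipation
  (RT < 0.1 s, configurable), accurate/inaccurate by direction.

**Filtering.** `compute_velocity` applies no smoothing by default, but the
end-to-end pipeline default low-passes position at 10 Hz (zero-phase,
2nd-order Butterworth) before differencing. Differentiating raw 60-Hz
positions with 0.05° noise yields ~2.1°/s speed noise per axis, which
false-triggers the 5°/s two-consecutive-sample rule on a substantial
fraction of trials at realistic RTs; low-pass filtering before
differentiation is standard practice for sampled kinematics and restores
reliable detection. The zero-phase pass extends the record start by even
(mirror) reflection — trials begin at rest, and an even extension keeps
the boundary slope of noise near zero — and the end by the usual odd
reflection (the record may end on the spring-return tail).

Scale consistency: all thresholds live in a configuration object, so
expressing positions in other units with rescaled thresholds leaves
detected indices unchanged (property-tested).

## Aggregation and statistics

Summaries pool all analysis blocks of a subject-day (familiarization
excluded). Accuracy = accurate / (accurate + inaccurate); omissions and
anticipations leave the denominator, since accuracy is about direction
choice. Mean RT uses accurate trials only; movement time, amplitude and
peak velocity include inaccurate trials by default (configurable). RT cost
is defined only where both conditions have at least one accurate trial.

The within-subject ANOVA is the classical balanced decomposition with
subjects as a random blocking factor: each effect is tested against its own
effect-by-subject interaction (the highest-order interaction serves as the
two-factor interaction's error). One- and two-factor designs are supported;
a Greenhouse–Geisser correction is available but off by default. The
implementation is cross-checked in the tests against statsmodels' AnovaRM
and against a brute-force sequential-OLS oracle (agreement to ~1e-13 in F).

Wilcoxon signed-rank: zero differences dropped; exact two-sided p by full
2ⁿ enumeration of sign assignments for n ≤ 12 (ties get average ranks),
otherwise a normal approximation with tie-corrected variance and a 0.5
continuity correction (within 0.014 of exact at n = 12 over 200 random
datasets; without the correction the gap exceeds 0.03). Pearson correlation
and the two-sample t test (Welch default, pooled optional) delegate to
scipy behind the module surface. The outlier rule flags values above
mean + 2.5 SD (one-sided high, as specified; a two-sided variant is
configurable) and reruns the requested analysis without the flagged
subjects, reporting both results. α = .05 throughout; no multiple-testing
correction across dependent variables (none is part of the analysis plan).

## Cohort table and FA ratio

The packaged 16-row participant table reproduces every printed column mean
at printed precision under **half-up rounding** — except UE FM, whose
printed mean (43.3) is inconsistent with its own sixteen row values (mean
42.0); the fixture keeps the row values and the discrepancy is documented
rather than forced to agree. The FA-ratio operation takes pre-extracted FA
arrays per hemisphere (image-space processing is upstream and out of
scope), thresholds at FA > 0.2, and divides the lesioned by the
non-lesioned mean.

## Validation studies and problem sizes

- **Detection recovery**: 1,000 independent trials at 0.05° noise; onset
  within 1 sample, offset within 2, direction recovery on error-free
  trials, median |RT error|.
- **Null calibration**: 2,000 summary-level null replicates (16 subjects,
  2 × 4 design, Gaussian subject offsets + noise); per-effect rejection at
  α = .05.
- **RT-cost decline recovery**: 200 replicate cohorts of 16 subjects on a
  reduced schedule of 24 trials per condition per day (one block — the
  full 96-trial schedule only shrinks the already-small trial-sampling
  error); each replicate compares the pipeline's estimated Day-1→Day-4
  group decline with the realised latent decline and tests the day effect
  on RT cost.

## What the synthetic studies do and do not show

The generator produces grid-aligned minimum-jerk movements with Gaussian
position noise. It does not model tremor or spasticity-related
irregularity, submovements or corrective re-accelerations, drift of the
spring center, y-axis curvature, or trial-to-trial variation in movement
duration and hold time. Detection-recovery results therefore demonstrate
the correctness and calibration of the measurement chain under the stated
noise model, not detector performance on pathological kinematics; on real
impaired-limb data the offset rule in particular (which assumes a clean
deceleration) would face submovement merging that these tests cannot
reveal.

## Known limitations

- The onset fallback clause is implemented only as a documented,
  off-by-default variant (as printed it fires at rest).
- The ANOVA assumes a complete balanced design and rejects missing cells
  rather than estimating them.
- Lognormal RT and linear mean trajectories across days are conveniences;
  the pipeline makes no distributional claims about real data.
- The growth-curve cohort model pins only Day-1/Day-4 moments; covariances
  involving Days 2–3 are modeling choices.
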