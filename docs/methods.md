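# Methods

`gaitintent` is an offline locomotor intent-recognition pipeline for
bilateral lower-limb neuromechanical recordings, driven by a synthetic
gait-signal generator that emulates the statistical structure the analysis
assumes. This note documents the models, the parameters that matter, and
the design decisions taken where the design was genuinely open.

## The recognition problem

A subject walks circuits of five locomotor modes — level walking (LW),
ramp ascent/descent (RA/RD), stair ascent/descent (SA/SD) — transitioning
freely between them. At every heel contact (HC) and toe off (TO) on either
leg, an intent-recognition controller must predict the mode of the step
that is beginning, using only a 300 ms window of signal ending at the
event. Decisions are *steady-state* when the incoming and outgoing modes
agree and *transitional* otherwise; transitional decisions are rarer and
harder, and are the ones that matter most for assistive-device safety.

The sensor suite per leg: seven surface-EMG channels (TA, MG, SOL, VL, RF,
BF, ST) at 1 kHz; knee and ankle goniometers (sagittal angle) at 500 Hz;
6-axis IMUs on thigh and shank at 500 Hz. Bilaterally: 22 sensors, 42 raw
channels, 46 analysis channels once knee/ankle angular velocities are
derived, and 332 features (166 per side: 7×10 EMG + 16×6 mechanical).

## Synthetic data model

No recordings ship with the package; the generator is first-class code and
defines the study conditions.

**Templates.** Every channel has a periodic gait-cycle template expressed
as a 6-harmonic Fourier series of gait phase (phase 0 = heel contact).
All five modes share per-channel base coefficients drawn once per seed;
mode *m* adds `separation × perturbation_m`, with perturbations drawn per
mode and channel. At `separation = 0` the modes are identical; the mean
pairwise template distance grows linearly with `separation` (default 1.0,
chosen so that default-noise error rates land in the single-digit-percent
regime typical of this task). The sagittal shank gyroscope is special: its
base waveform is designed, not random — a dominant positive mid-swing peak
(~300 deg/s at phase 0.8) flanked by toe-off (phase 0.6) and heel-contact
(phase 1.0) minima — and its mode perturbation is kept small so the
morphology the segmentation method relies on survives any separation
setting. Ground-truth event phases are located numerically on the
harmonic-truncated template so that generator events coincide with the
waveform minima the detector searches for.

**Stride timing.** Both legs share a piecewise-linear stride-clock-to-time
warp with per-stride duration jitter (cadence 1 stride/s, SD 5%; typical
self-selected walking). The legs walk in antiphase: left-leg events sit
exactly half a stride from right-leg events on the shared clock.

**EMG.** Each EMG channel is a unit-variance broadband carrier (white
noise band-passed 20–450 Hz, matching surface-EMG front-end hardware)
amplitude-modulated by a non-negative phase/mode envelope. EMG features
are therefore irreducibly stochastic even at zero measurement noise —
a 300-sample window estimates the envelope with finite precision.

**Transitions.** Terrain changes at segment boundaries of a circuit. The
within-stride instant of each change is randomized but alternates between
early-stance and late-stance halves, so both HC- and TO-triggered
transitions receive training coverage even at small sample sizes. At each
transition one leg (chosen at random) leads:

* the *leading* leg's signals ramp from the old to the new mode template
  over `anticipation` (default 0.2) strides before its first new-mode
  step, reaching weight 0.85–1.0 at the event — it is about to step onto
  the new terrain and its own signals say so;
* the *trailing* leg shows a strong postural-adjustment bump (weight
  0.70–0.90) over the 0.15 strides while the leading leg commits, decaying
  to 25% of its peak before the trailing leg's own weak anticipation ramp
  (0.25–0.40) half a stride later.

The trailing leg's upcoming transition is therefore carried mainly by the
*contralateral* (leading) side, which fully committed half a stride
earlier — the mechanism that makes bilateral sensor fusion pay off, and
the quantity the `transition_lead` parameter (default 0.5 strides)
controls. In the noiseless limit every transition is still recoverable
from either side alone, so classification error vanishes as noise does.

**Noise.** Two stochastic terms: (i) additive white measurement noise,
`noise_sd` (default 0.25) times each channel's template SD; (ii) slow
multiplicative amplitude drift modeled as 3 shared ~1 Hz latent processes
with per-channel Gaussian loadings (`drift_sd` = 0.10 total SD). The
low-rank structure matters: wearable drift sources (speed changes,
electrode impedance, temperature) modulate many channels coherently, and
independent per-channel drift would create unrealistically high-rank noise
that swamps covariance estimation at desk-scale sample sizes.

**What the generator does not emulate:** musculoskeletal dynamics,
electrode crosstalk or shift, foot-clearance variability, fatigue-related
spectral compression of EMG, and subject-specific asymmetries beyond the
per-seed template draw. Passing tests show the *pipeline* recovers planted
structure under the stated noise model; they are not evidence about any
particular real recording system.

## Labels and the transition-straddling exclusion

Each leg's mode label switches at its own first step in the new terrain,
so the leading leg's first new-mode step begins `transition_lead` strides
before the trailing leg's. This per-leg labeling creates, per transition,
a short span during which the legs' labels disagree. A decision whose step
begins inside that span — other than the transitional decision itself — is
genuinely ill-defined: feature-wise the body is mid-transition, label-wise
the step is "steady". `label_events` excludes such decisions by default
(`drop_straddling=True`), in the spirit of excluding ambiguous strides
from offline evaluation; roughly one decision per transition is dropped.
Labels are evaluated 50 ms after the event time so detector jitter cannot
push a transitional label onto a neighboring step.

## Preprocessing

All analysis-path filters are causal (forward-only) Butterworth cascades
realized as second-order sections: the framework emulates a real-time
controller for which future samples do not exist. EMG: 6th-order 20 Hz
high-pass, then three 6th-order band-stops with stopband edges ±3 Hz
around 60/180/300 Hz (the "6 Hz width" is read as edge-to-edge).
Goniometer/IMU: 6th-order low-pass at 10/25 Hz. Knee and ankle angular
velocities are centered differences of the filtered angles and are
appended as goniometer channels. The first 0.5 s of every trial is
excluded from windowing (filter warm-up).

## Gait segmentation (dual-minima)

Events come from the sagittal shank angular velocity, low-pass filtered
with a 1st-order 6 Hz Butterworth. Mid-swing = local maxima above
50 deg/s separated by ≥0.5 s; toe off = the signed minimum in the 0.4 s
before each mid-swing peak; heel contact = the minimum in the 0.4 s after.
Peaks lacking a full search window are dropped. Segmentation is an
*offline* step, so the pre-detection filter is applied zero-phase
(forward–backward): a causal first-order filter at 6 Hz would bias event
times by ~20–27 ms, consuming most of the ±30 ms timing budget, without
any corresponding benefit. The detector thresholds are deliberately not
tuned per subject. On synthetic trials with gyro noise up to 10% of the
mid-swing peak, ≥99% of interior ground-truth events are recovered within
±30 ms (median error well under 10 ms).

## Features

Per event and channel, one window of the channel's native rate (300
samples at 1 kHz, 150 at 500 Hz), ending at the event; the delayed variant
spans −210 ms to +90 ms. EMG: MAV, waveform length, zero crossings, slope
sign changes (deadband ε, default 0 for synthetic data with a known noise
floor), and six AR coefficients — estimated by Burg's method (stable on
300-sample windows) in the prediction convention, innovation variance
excluded, giving exactly 10 features/channel. Degenerate windows (constant
or exactly periodic) get zero AR coefficients with a warning. Mechanical:
mean, SD (n−1), max, min, and the literal first/last window samples.

## Mode-specific classification

One classifier per (leg × event type × incoming mode) — 20 cells — each
restricted to the legal outgoing modes: from LW all five modes, from any
other mode only {itself, LW}. Routing uses the incoming label; a
prediction outside the legal set is structurally impossible and is also
hard-asserted. Per cell: z-score normalization and PCA fitted on that
cell's training rows only (no leakage), then LDA (equiprobable priors,
PCA retaining ≥95% variance by default), a linear one-vs-one SVM (C=10),
or an MLP (one hidden layer of 10 tanh units, SGD with momentum 0.9,
adaptive learning rate initialized at 0.1, epoch cap 500, seeded
initialization — the cap and seeding are this package's choices, since no
stopping rule is inherent to the scheme). Classes are coded in the fixed
mode order LW, RA, RD, SA, SD, which also resolves ties. Cells with a
single observed class, or fewer rows than classes, degenerate to a
majority-class constant predictor. The powered-prosthesis variant is a
configuration: PCA to 50 dimensions, merged LW/RA classes, delayed
windows.

Evaluation is randomized k-fold cross-validation (default k=10) at the
event-row level — the most literal reading of randomized fold assignment;
circuit-level grouping was considered and not taken, since replicate
circuits are independent draws here. Error rates are reported per
(leg × event type) cell, split into steady-state and transitional, and
aggregated as the unweighted mean of the four cells.

## Sensor selection

Sequential forward selection starts from all 11 ipsilateral sensors and
greedily adds the contralateral sensor minimizing cross-validated overall
error; all features of a sensor enter together, ties resolve to the
canonical sensor order, and the same fold partition (same seed) is reused
for every candidate within an iteration so the arg-min is not dominated by
partition noise. Errors may rise in later iterations; the trace records
but never prunes.

## Experiment scale and statistics

"Subjects" are replicate generator seeds: each draws its own templates
(inter-subject variability) and its own trials. The default study runs 10
seeds × 2 standard circuits (LW–SA–LW–RD–LW and LW–RA–LW–SD–LW) × 8
repetitions × 4 strides per segment, ~1100 decisions per seed — a
desk-scale analogue of the benchmark protocol (which used ~25 circuit
repetitions per subject). Paired comparisons use the classical paired t
with explicit Bonferroni `family_size` (the comparison family is an
analysis choice, so the divisor is an argument, not an inference), plus an
exact paired sign test for the directional laterality hypothesis.

Under these conditions the bilateral fused sensor set yields lower
transitional error than the ipsilateral set for essentially every seed
(sign test p < 0.05), and adding the single best contralateral sensor —
almost always a kinematic one (shank IMU, thigh IMU, or a goniometer) —
reduces overall error below the all-ipsilateral baseline. These are
computed fresh by `scripts/acceptance.py` and the acceptance test suite;
no empirical number in this note is asserted beyond what those runs
compute.

## Known limitations

* Contralateral-only *single-modality* sensor sets retain a small error
  floor even in the noiseless limit: at the leading leg's decisions their
  only evidence is the trailing leg's brief postural bump. The fused
  contralateral set does reach the <1% separable-limit regime.
* The straddling-decision exclusion couples labeling to the availability
  of both legs' label timelines; on unilateral data it is a no-op.
* Burg sign conventions for AR features differ across the literature; the
  prediction convention used here is validated by parameter recovery on
  known AR(6) processes, but feature values are not interchangeable with
  implementations using the forward-model sign.
* The generator's transitions blend templates linearly; real transitions
  also change cadence and stride geometry.
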