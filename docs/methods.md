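# Methods

This note documents the models, conventions and numerical choices behind
`gaitfatigue`: what each stage assumes, which parameters matter, what the
synthetic test bed does and does not emulate, and where the design was
genuinely open.

## Signals and units

A recording holds 16 synchronised channels at a fixed sampling rate
(110 Hz by default): seven regional plantar forces in newtons (hallux Hx,
medial metatarsal MM, posterior of footpad POF, lateral metatarsal LM,
medial arch MA, lateral arch LA, heel H), triaxial acceleration in m/s²,
triaxial angular velocity in deg/s, and rotation angles in degrees for the
sagittal, coronal and transverse planes. Units are fixed by the schema and
never inferred from files; timestamps are optional on ingest and
reconstructed as i/fs. The axis-to-plane sign conventions of a specific
IMU mounting are not modelled; the schema fixes names only.

## Gait-cycle segmentation

The thresholded signal is the **sum of all seven regional forces** — the
best available proxy for vertical ground reaction force from discrete
sensors (which specific signal should carry the classic 10 N event
threshold is an open choice; total force is ours and is configurable).
Events are debounced: a below-threshold run shorter than `min_swing_s`
(0.1 s) inside stance is chatter, not a toe off; an above-threshold run
shorter than `min_stance_s` (0.2 s) inside swing is a blip, not a heel
strike. The same rule applies at the recording head, so a recording that
starts mid-ramp does not open a spurious first cycle. Cycles are half-open
spans [hs, next_hs), so consecutive cycles tile the record without double
counting. Incomplete leading/trailing cycles are discarded; a series that
never crosses threshold yields an empty cycle list, not an error.

The flat-foot window is 15–25 % of the cycle (foot-flat and heel-off sit
near 10 % and 30 %, so this span is quiescent mid-stance). Sample indices
are rounded half-away-from-zero and the window is half-open; cycles
shorter than 8 samples cannot host a non-empty window and are rejected as
degenerate.

## Features

All 49 features are computed per cycle and averaged across the cycles of a
window (assignment by heel-strike containment; the mean is the
conventional window statistic — the aggregation statistic is configurable
in principle but only the mean is implemented).

Conventions that matter:

* **CV** is the sample standard deviation (n−1) over the absolute mean.
  When |mean| < 1e−9 in signal units the ratio is meaningless; the value 0
  is returned with a logged flag rather than an infinity that would poison
  model training.
* **Region contact features** use a 1 N contact threshold, deliberately
  far below the 10 N cycle threshold: the small arch sensors carry only
  about 1 N·s of impulse per cycle and would be zeroed at 10 N. Impulse is
  the discrete integral over above-threshold samples, each contributing
  its full 1/fs dwell — this equals the trapezoidal rule whenever force
  vanishes at the contact edges and assigns a constant 50 N contact of
  0.5 s exactly 25 N·s. PF is the maximum over the whole cycle, so a
  region that never reaches threshold still reports its (sub-threshold)
  peak, with CT = Imp = FCV = 0.
* **FCV is within-cycle** variability over the above-threshold samples
  (then averaged across a window's cycles), consistent with all features
  being per-cycle quantities; cross-cycle variability is a different
  statistic and is not what the per-cycle table defines.
* **Jerk and angular acceleration** are central finite differences scaled
  by fs (one-sided at cycle edges; exact for linear signals), taken per
  axis before the resultant norm.
* **Angle features are Max / Range / CV** of the drift-corrected angle.
  Re-referencing subtracts the mean angle over the flat-foot window from
  the whole cycle; it is idempotent, removes constant offsets exactly, and
  removes slow drift up to the amount accumulated within one cycle. The
  correction is applied to all three planes, not only the transverse one:
  the yaw angle drifts worst in practice, but "rotation relative to the
  stationary stance phase" requires the same referencing everywhere.
* **Resultant-signal statistics** default to the full cycle; a
  `swing_only` switch restricts them to toe-off→next-heel-strike for
  analyses that treat angular variability as a swing-phase quantity. The
  full cycle is the default because it needs no extra event and the
  swing-phase interpretation remains visible through it.

## Windowed dataset

stride = window − overlap (default 10 − 8 = 2 s). Two counting modes:

* `formula`: count = ⌊segment/stride⌋ — the stride-based bookkeeping that
  yields 150 windows for a 5-min segment. Windows start at 0, stride, …,
  keep their nominal length, and are truncated only at the end of the
  available recording. State segments are slices of a continuous walk, so
  the simulator pads each segment with one extra window length of cycles
  (`pad_s`, default 10 s) and trailing windows are backed by full data;
  truncation at the segment end is the special case of an unpadded
  recording.
* `strict`: count = ⌊(segment − window)/stride⌋ + 1, fully contained
  windows only (146 for a 5-min segment).

Windows with fewer than `min_cycles_per_window` (3) complete cycles are
dropped with a logged count; a participant segment yielding no windows is
excluded with a warning. Labels are pure functions of segment membership —
a window can never straddle states because each state is its own
recording.

## Synthetic gait simulator

The simulator emulates the study conditions the pipeline is designed for:
18 participants, one 5-min segment per state, 110 Hz. Each participant's
template is drawn once from between-subject dispersions (10 % SD on force
peaks and angle amplitudes, 0.05 s SD on the 1.1-s cycle duration) using
substreams of a single cohort seed, so partial re-runs are reproducible.

Waveforms are closed-form functions of cycle phase:

* Regional forces are raised-cosine bumps inside per-region activation
  windows, scaled to region peaks (heel 60 N, metatarsals/footpad
  25–35 N, arches ≈ 5.5 N — the arch peaks are calibrated so the sampled,
  thresholded impulse is ≈ 1 N·s, matching what small-area arch sensors
  record). Bumps are smooth, integrable in closed form, and give exact
  control of peaks and impulses.
* Rotation angles are piecewise-smooth bumps with an exact plateau over
  10–55 % of the cycle, so the flat-foot quiescence assumption holds in
  ground truth by construction. Sagittal excursion defaults to 22° swing
  with an 8° early-stance dip.
* Angular velocity is the analytic derivative of the angle trajectories
  plus a three-phase oscillatory component (axes phased 120° apart,
  default 15 deg/s, 7 cycles per gait cycle). The three-phase layout makes
  the oscillation's resultant magnitude constant, so its amplitude floors
  the resultant angular acceleration and the angular-acceleration CV is
  provably monotone decreasing in it — the handle used to inject the
  fatigue effect on that CV.
* Noise is additive Gaussian per channel (defaults: 0.5 N, 0.15 m/s²,
  2 deg/s, 0.25°), with forces clipped at zero; drift is a linear ramp on
  the transverse angle (0.05 deg/s).

Fatigue deforms the template in the directions reported for fatigued gait:
arch impulses ×1.30 (via arch peaks — exact multiplicative shift on the
clean waveform), sagittal Max and Range ×1.20 (via all sagittal
amplitudes — exact, and necessarily shared, since Max and Range scale with
the same knob), and angular-acceleration CV ×0.70 (directional, via the
oscillation amplitude; the exact magnitude is waveform-dependent). The
paper-style effect *directions* are fixed; their *magnitudes* are config
choices, because significance levels do not determine effect sizes.

Alongside each recording the simulator emits a per-cycle ground-truth
feature table computed from the clean signals by direct, self-contained
formulas (its own threshold scan and feature arithmetic, not calls into
the extraction code), which is what segmentation and extraction are tested
against.

A second generator, `simulate_feature_cohort`, draws window samples
directly in feature space: every feature is a per-participant Gaussian
baseline (SD 0.25) plus within-participant noise (SD 1.0), and exactly
five named features — the two arch impulses, sagittal Max and Range, and
the angular-acceleration CV — receive a fatigue shift of d pooled standard
deviations (default d = 2, CV-type features shifted down). The waveform
simulator cannot express "exactly k informative features" because scaling
one waveform parameter co-moves every feature derived from it (e.g. arch
peak force with arch impulse); the feature-space cohort exists precisely
for selection and recovery experiments that need that control.

**What passing tests do and do not show.** The simulator's waveforms are
smooth, stationary and strictly periodic up to noise; real gait has
step-to-step autocorrelation, speed drift, asymmetries, occasional missed
contacts and sensor saturation, none of which are modelled. Tests against
the simulator therefore validate the *mechanics* of the pipeline
(segmentation, feature arithmetic, selection, evaluation, bookkeeping) and
its behaviour under controlled effect injections — they do not certify
classification accuracy on real recordings.

## Selection, models, evaluation

* Stratified fivefold CV with one fixed seed for all selection steps, so
  every candidate is scored on identical folds (fold-level comparability
  is what makes greedy scores commensurable). Stratification is at the
  sample level; grouping folds by participant during selection is a
  reasonable alternative that was not adopted as the default.
* The stopping rule is a literal strict decrease (no tolerance). Chance
  fluctuations of the CV rate can admit a noise feature or two; the
  selection trace records every step so this is auditable.
* Ties are broken by canonical feature-table order — deterministic and
  auditable.
* Misclassification rates are pooled counts (misclassified / total), never
  averages of per-fold rates, so rate = 1 − accuracy holds exactly.
* Hyperparameter search is a seeded, budget-limited random search over
  conventional spaces (SVM: C ∈ 10^[−2,3], γ ∈ 10^[−4,1]; KNN: k ∈ [1,30],
  uniform/distance weights; DT: depth ∈ [1,30], min leaf ∈ [1,20]; NB:
  variance smoothing ∈ 10^[−12,−6]), minimising the fivefold rate — the
  expected misclassification cost under uniform costs, which is the right
  loss here because the classes are balanced by construction (150 + 150
  windows per participant). Candidate 0 is always the default spec, so the
  incumbent is never worse than the default on the search folds, and
  budget 1 reduces to evaluating the defaults.
* Standardization (z-score) is applied for SVM and KNN only, fit on
  training folds exclusively; the fitted per-fold scaler means are exposed
  so leakage is testable. NB and DT are scale-free and run raw.
* Source ablation re-runs selection inside each source's subset
  (28 force / 21 IMU / 49 dual) rather than reusing the dual-source set,
  so each source is judged by its own best subset.

## Statistics

The paired Wilcoxon signed-rank test drops zero differences, midranks
ties, and uses the exact null distribution — enumerated over all 2^n sign
assignments — for n ≤ 12 (two-sided p = probability of |W⁺ − n(n+1)/4| at
least as extreme). For larger n it uses the normal approximation with tie
correction and a continuity correction of 0.5 toward the mean. The
in-package implementation exists because the standard exact routines do
not handle midranked ties; tie-free cases agree with scipy's exact mode to
1e−12. Bonferroni flags are pᵢ < α/m with m = the number of features in
the tested (selected) set. Pearson correlations report a flagged 0 for
zero-variance features instead of an undefined value.

## Known limitations

* The simulator does not model speed/incline variation, turning, or
  left/right asymmetry; all features are right-foot, per the single-insole
  design.
* The fatigue effect on the angular-acceleration CV is injected
  directionally, not at an exact magnitude.
* Frequency-domain features, body-weight normalisation and probability
  calibration are out of scope.
* Real-device concerns (Bluetooth ingestion, on-device inference, latency)
  are not part of this package.
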