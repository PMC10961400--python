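# Methods

`ppgstiff` estimates aortic stiffness — carotid–femoral and aortic pulse
wave velocity (cfPWV, aoPWV, m/s) — from a brief finger photoplethysmogram
(PPG), optionally combined with a single-lead ECG. This note documents the
signal model, the processing chain, the feature system, the statistical
machinery, and the design decisions taken where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The scientific problem

Aortic stiffening shifts wave reflections earlier and enlarges them, which
reshapes the peripheral pulse: the reflected wave fuses with the direct
systolic wave, the dicrotic notch fades, and in stiff subjects the direct
peak survives only as an inflection (anacrotic notch) on the upslope of a
reflection-dominated pulse. Features of the finger-PPG pulse and of its
first (VPG) and second (APG) derivatives therefore carry stiffness
information. Two obstacles make this hard in practice: (i) the conventional
systolic-peak landmark S no longer marks the direct wave once fusion sets
in, and (ii) many catalogue features repeat poorly between visits.

The package addresses both: a tangent-based estimator of the first
(direct) systolic peak `p1` that works on all six finger-PPG morphology
classes (1, 1′, 2, 3, 3′, 4), and a repeatability gate (within-subject
coefficient of variation, WSCV < 20%) applied before any modelling.

## Synthetic waveform model

No public dataset accompanies this problem, so the package ships a
first-class simulator (`synth_pulse`) that generates multichannel records
(PPG, stylized single-lead ECG, finger-BP) with exact ground truth.

**Beat model.** Each pulse is a sum of Gaussian wave components on one beat
period, rebased by the chord through its endpoints so consecutive beats
concatenate with an exact local minimum at every onset:

* a **direct systolic complex** — a narrow *upstroke* Gaussian plus a
  broader *body* Gaussian. A single Gaussian would place the maximal
  deceleration (APG minimum, landmark b) exactly at the peak, which would
  collapse `Am b` onto `Am p1`; real pulses decelerate hardest on the late
  upslope, below the peak, and the two-Gaussian complex reproduces that
  shoulder geometry;
* a **reflected wave** whose delay after the direct wave shrinks and whose
  relative amplitude grows with the latent stiffness;
* a broad **diastolic runoff** wave that keeps the pulse decaying into the
  next onset (a V-shaped foot), as in real PPG; without it the inter-beat
  baseline is flat and foot detection becomes noise-dominated.

**Latent stiffness.** A single subject-level parameter s (m/s, simulation
range 4–12, emulating a healthy-to-stiff adult cohort) drives the beat
morphology monotonically through four affine maps (per-class parameters in
`ppgstiff.config.CLASS_PRESETS` / `WAVE_SHAPE`): reflection delay ↓,
reflection amplitude ↑, and the shoulder of the direct complex separates
further from (and sits relatively lower than) the effective first peak —
an augmentation-coupled shoulder. The six class presets set the regimes
(1/1′ distinct direct peak and separate diastolic wave; 2 shallow notch;
3/3′ fused, 3′ with the direct complex smaller than the reflection, which
produces the anacrotic inflection; 4 a near-single hump). Within every
class all maps are strictly monotone in s, so the ground-truth reflection
delay, and the key feature `Am b/Am p1`, respond monotonically — the
simulator realizes, rather than assumes, the negative stiffness–feature
association the method is built around.

**Records.** Beats are drawn with period 60/HR (default 60 bpm) and an
inter-beat-interval SD of 2% of the mean — chosen so a 20-s window's pulse
rate variability typically falls in the accepted 5–10% band. The ECG
channel is an impulse train preceding each PPG foot by the pulse arrival
time (default 206 ms; with the default 1.76 m height this reproduces a
height-normalized PAT near 117 ms/m). The BP channel is the same mixture
with 20% narrower waves leading the PPG by a configurable 25 ms (20–30 ms
range). Additive white noise (default SD 0.02 of unit pulse amplitude) and
slow baseline wander (amplitude tied to the noise level, 0.18 Hz) complete
the record; `noise_sd=0` yields exactly clean waveforms. All randomness
descends from one integer seed through named substreams; identical inputs
give bit-identical records.

**Cohorts.** `make_cohort` draws ages uniformly on 21–66 y, ties stiffness
to age with between-subject scatter (SD 0.8 m/s), draws classes uniformly
(the field does not report class prevalence), assigns anthropometry and BP
with stiffness-linked means, and emits one or two visit records per subject
(visit 2 perturbs HR by SD 2 bpm and stiffness by SD 0.15 m/s). Outcomes
are cfPWV = s and aoPWV = 0.9 + 1.05 s plus observation noise (default SD
0.3 m/s; 0 makes outcomes an exact monotone function of stiffness).

**What the simulator does not emulate.** Motion artifacts, vasomotor and
respiratory amplitude modulation, skin-tone/perfusion optics, sensor
nonlinearity, and true vascular transfer functions are all out of scope. A
passing suite therefore demonstrates correctness of the algorithms under
the stated waveform model, not field performance on human data.

## Processing chain

1. **Bandpass** 0.35–20 Hz (ECG: 5–30 Hz), order-2 Butterworth applied
   forward–backward (`sosfiltfilt`): zero phase, so fiducial timing is
   never shifted. Sampling below twice the upper edge is rejected.
2. **Beat onsets**: peaks of the smoothed slope locate each systolic
   upslope; the onset is the preceding valley minimum refined to the point
   where the slope first reaches 5% of that beat's maximal upslope. The
   refinement compensates the few-millisecond leftward pull that the 20-Hz
   edge exerts on a V-shaped foot; on clean simulated records detected
   onsets match ground truth within 5 ms.
3. **R-waves**: peaks of the squared filtered ECG above an adaptive
   threshold with a 250-ms refractory distance.
4. **Beat quality** (per beat, with reason codes): rate within 40–180 bpm;
   inter-beat interval ≤ 3 s; window max/min interval ratio ≤ 2.2;
   correlation with the leave-one-out mean beat template ≥ 0.86. These are
   the published pulse-oximetry signal-quality thresholds; all are
   config-overridable.
5. **Stable window**: the earliest 20-s span in which every beat passes
   quality and the pulse rate variability — defined here as
   (max IBI − min IBI)/mean IBI × 100, the source protocol names the band
   but not the formula — lies within 5–10%. Earliest-window tie-breaking
   keeps the pipeline deterministic; failure raises an error carrying
   per-criterion failure counts.
6. **Ensemble average**: each beat resampled to L = 1000 samples (1-ms
   granularity at the native 1 kHz), min–max normalized *per beat*, then
   averaged and re-normalized to span [0, 1] exactly. Per-beat-then-average
   ordering is a documented choice (the alternative, normalize-after,
   weights beats by amplitude). VPG/APG come from Savitzky–Golay
   differentiation (window 31, order 3): raw finite differences amplify
   noise and destabilize APG landmarks.

## Fiducial points

On the averaged beat: O (first sample, t = 0), S (global maximum), w
(first VPG maximum), the alternating APG sequence a–f, N (first strict
pulse minimum after S), D (first pulse maximum after N), y (first VPG
minimum after the systolic complex) and z (next VPG maximum). All extremum
locations get sub-sample parabolic refinement — this keeps amplitude
ratios continuous in the underlying morphology instead of stepping with
the sample grid. Equal-height extrema resolve to the earliest. A landmark
that does not exist on a morphology (no notch on a fused beat, no d/e/f on
a single-component pulse) is reported absent with a reason and never
fabricated; features requiring it become missing values.

*Notch fallback.* The classic heuristic locates N via the APG e-wave. With
a 2–4 Gaussian beat model the post-peak APG sequence does not reliably put
e at the notch (the model lacks the late-systolic ripple of real APG), so
N is defined directly as the first strict pulse minimum after S — which on
separated-wave classes lands between the direct and reflected waves, as it
should — and the e-wave remains available for cross-checking.

**The tangent-based p1.** After w the VPG falls along an initially linear
downslope. A straight line through that linear portion crosses zero at the
time of the first (direct) systolic peak even when the pulse itself shows
no distinct peak there. The "initial linear part" is operationalized as
the tangent at the APG minimum b — the point where the VPG slope is
locally stationary — giving

    t_p1 = t_b − VPG(t_b) / APG(t_b),

i.e. one Newton step on the VPG from b. A least-squares variant
(`p1.method = "ls-fallback"`) fits the line over the maximal contiguous
span around b where APG stays within 10% of APG(b); both variants are
exposed in config. On a symmetric single-Gaussian pulse the APG minimum
sits exactly at the peak where VPG = 0, so the construction is analytically
exact there — the module's anchor test. p1 is reported absent (never
guessed) if the VPG has no downslope after w, the APG has no negative
minimum, or the zero crossing falls outside the beat. x shares the p1
timestamp; y is recomputed as the first VPG minimum after x.

## Features

The registry (`features.registry`) holds 136 established definitions —
times, pulse amplitudes and derivative values at landmarks, APG ratios
(b/a … and ageing-type indices such as (b−c−d−e)/a), amplitude ratios
against S and D, time ratios against the beat duration, landmark-interval
spans, pulse widths at seven height levels (systolic/diastolic/total and
their ratios), areas (including the inflection-point area ratio A2/A1),
segment slopes, and pulse statistics — plus 17 engineered features, 13 of
which use p1 (`Am b/Am p1`, `Am c/Am p1`, `Am p1/Am S`, `Tm x/Tm ss`,
`ms`, `k v2`, …). The full composition of the established catalogue varies
between publications; this package pins its interpretation in a
machine-readable manifest (`features.manifest()`) so any substitution is
explicit, never silent. Definitions interpreted rather than transcribed:

* `ms` — mean systolic upslope, `ppg(p1)/t(p1)` on the normalized beat;
* `Tm ss` — onset-to-onset time, i.e. the beat duration;
* `Tm SD`, `Tm ND` — S→D and N→D spans;
* `k v2` — spring-constant-type index, `−APG(p1)·T²/ppg(p1)`
  (dimensionless; for a harmonic oscillator −APG/amplitude is ω²).

Every feature gets a heart-rate-adjusted variant (plain division by HR in
bpm, suffix " HR") at extraction. Amplitude-ratio features are invariant
to rescaling the raw signal; time features scale with beat duration while
time ratios do not — both are property-tested. MAP uses
DBP + (SBP − DBP)/3. The estimated PWV (ePWV) uses the published
normal-population equation on mean BP = DBP + 0.4 (SBP − DBP); its
coefficients live in config, not code, so they can be re-validated against
their source. (That equation is quadratic in age with a shallow vertex in
the mid-20s; monotonicity tests start at age 30.)

## Repeatability, filtering, agreement

Two-visit panels are averaged cellwise (a value present for one visit
passes through; both-missing stays missing). CV keeps the sign of the
mean. WSCV uses the RMSE method, 100·√(Σdᵢ²/2n)/grand mean, checked
against a scalar-arithmetic oracle to 1e−10. Feature filtering drops
zero-variance columns, then columns with WSCV ≥ 20%; extreme cells beyond
3×IQR outside the quartiles are *flagged, not removed* — the protocol
defines the check but no removal action, and flagging preserves data. The
filter audit log plus surviving columns exactly partition the input.
Bland–Altman reports bias and limits of agreement at ±1.96 SD of the
errors alongside RMSE and R².

## Modelling

Participants are split 80/20 (rounded; split at the participant level —
visits are already averaged). Hyperparameters (LASSO penalty on a 16-point
log grid 1e−3…10; random-forest `max_features` and `min_samples_leaf`,
1000 trees) are chosen by lowest mean RMSE under repeated k-fold
cross-validation — 10 folds × 50 repeats by default, matching the
small-cohort protocol; quick runs may lower the repeat count, and the
bundled experiments use 3 repeats with the same grid. Median imputation,
centering/scaling and tuning are all computed on the training split only
and frozen; features missing for >10% of training participants are
dropped. A panel left with no informative columns falls back to an
intercept-only mean predictor. Both R² conventions are computed —
1 − SS_res/SS_tot is the headline, squared Pearson correlation is reported
alongside — because they differ on test data and the choice is otherwise
ambiguous. Importances: |coefficient| for LASSO (exact zeros for dropped
features), permutation importance for the forest (negatives clipped),
rescaled so the top feature is 100; plain linear models return their
coefficient table. Test-set evaluation adds Bland–Altman agreement of
predictions against observations.

Leakage is asserted behaviorally: a canary feature equal to the outcome on
test rows and constant on training rows must leave the held-out RMSE
bit-identical — training-split-only processing necessarily discards it.

## Validation experiments and problem sizes

`tests/test_acceptance.py` and `scripts/acceptance.py` run the same
experiments (`ppgstiff.experiments`), at sizes chosen to exercise the full
pipeline at desk scale:

* p1 anchor on a single-Gaussian pulse at 1 kHz (error well under 1 ms);
* fiducial robustness over 6 classes × 200 random parameterizations
  (stiffness across the full range, beat periods 0.7–1.2 s): p1 success
  and zero ordering violations;
* WSCV vs brute force on 1000 random panels;
* `Am b/Am p1` strictly decreasing on a 20-point stiffness grid per class,
  and a negative univariate slope in ≥95% of 100 seeded 15-subject
  cohorts (template-level beats with outcome noise SD 0.3 m/s);
* noise-floor recovery: 20 single-visit cohorts of n = 200 (35-s records
  at 500 Hz, noiseless waveforms, outcome noise σ = 0.5 m/s), full
  record→features→model pipeline with LASSO and univariate linear
  regression; the best model's mean test RMSE must land in [σ, 1.3σ];
* the leakage canary on an 80-subject cohort.

## Known limitations

* The Gaussian-mixture beat is a morphological, not hemodynamic, model:
  no wave-intensity analysis, no tube-load physics; stiffness enters
  through prescribed monotone maps.
* The established-feature catalogue is a documented interpretation; counts
  are pinned by the manifest, individual formulas may differ from any
  specific prior enumeration.
* Onset detection is tuned for pulses with a V-shaped foot; signals with
  long flat diastolic baselines will localize feet less precisely.
* WFDB-format I/O is not included; records exchange as tidy CSV with a
  JSON sidecar.
* Model performance numbers on simulated cohorts characterize the
  pipeline, not clinical accuracy.
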