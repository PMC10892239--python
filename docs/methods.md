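# Methods

`olfalert` implements an end-to-end analysis of olfaction-modulated
driver alertness from multichannel EEG and brake reaction times, plus a
synthetic-data generator that emulates the study protocol so every
stage is testable without recorded data.  This note documents the
models, the numerical choices, and what the synthetic results do and do
not establish.

## Study protocol emulated by the generator

Each simulated participant drives two 60-minute monotonous sessions, one
per fragrance condition (*alerting* vs *relaxing*), with 19-channel
10–20-montage EEG at 500 Hz.  Brake events occur every 20–40 s (gap
drawn uniformly), yielding ~115–120 trials per session; the first event
is never within 10 s of session start so the 10-s pre-brake analysis
window always exists.  The fragrance is released at minute 30.  A
condition effect of duration `effect_duration_min` (default 15 min)
follows onset and then decays linearly to zero over `effect_decay_min`
(default 5 min) — the published behavioural difference vanishes in the
[45–60] min segment, and any decay reaching zero by minute 50 is
consistent with that; the linear 5-min ramp is the package's choice.

### EEG signal model

Each channel is a sum of:

* five band-limited oscillatory processes — white Gaussian noise passed
  through the zero-phase 4th-order Butterworth band-pass of each
  canonical band (delta 1–4, theta 4–8, alpha 8–12, beta 12–30, gamma
  30–40 Hz), normalized to unit RMS and scaled to per-band RMS
  amplitudes (defaults 8, 6, 10, 4, 2 µV).  Band-limited noise rather
  than sinusoids keeps the STFT spectrum realistically spread;
* a 1/f-power background (FFT-shaped white noise, default 4 µV RMS);
* optionally, artifacts: biphasic frontal blink transients (200–400 ms,
  amplitude 10× the background RMS, loading Fp1/Fp2 fully and F7/F8 at
  half; the positive lobe takes 75 % of the duration so the energy is
  concentrated below 4 Hz, as eyelid artifacts are) and 0.5–2 s
  bursts of 30–100 Hz noise on T3/T4 at 3× background RMS.

In the alerting condition, the alpha-band amplitude at the seven
frontal channels is multiplied by `1 − alpha_suppression` (default
suppression 0.3) over the effect window, so frontal alpha *power* drops
by `1 − (1 − s)²`.  A single shared alpha-band source is added to the
frontal channels and, delayed by 20 ms, to the parietal channels
(relative amplitude `source_gain = 0.6`), which guarantees a non-zero
imaginary cross-spectrum — hence detectable, condition-sensitive wPLI —
without any volume-conduction-like zero-lag component.

### Behaviour

Reaction times follow

    RT(t) = [base + drift·t + s(cond)·effect·w(t)] · exp(ε),  ε ~ N(0, σ²)

with `s(alerting) = −1`, `s(relaxing) = +1`, `w(t)` the same
plateau-then-decay ramp, base 0.7 s (the study reports standardized RT
only; 0.7 s is a typical braking RT and a free choice here), drift
0.003 s/min, effect 0.05 s and σ = 0.15.  The multiplicative lognormal
noise keeps RTs positive and right-skewed with a coefficient of
variation equal to σ.

Optionally (`rt_alpha_coupling > 0`), a per-epoch lognormal fluctuation
of the alpha amplitude at `coupling_channels` (default F8) is added to
the deterministic RT, creating a positive alpha-power–RT correlation of
the kind the correlational analysis is meant to detect.

Questionnaire scores (perceived alerting/relaxing character on the
1–5 scale, Karolinska Sleepiness Scale 1–10 before/after) are drawn as
correlated normal pairs (within-subject ρ = 0.5) at the reported
means/SDs, clipped to their scales.

### The trial-window fast path

`simulate_trial_epochs` synthesizes only the 10-s pre-brake windows
(identical per-window construction, alpha gain evaluated at the brake
time) instead of the continuous hour.  Replicate-cohort studies in the
tests and the acceptance script use this path at 125 Hz with reduced
trial counts (2–3 trials per 5-min epoch; the baseline epoch keeps ~8
so that baseline noise stays small relative to the epochs standardized
by it) and with artifacts disabled, since the artifact stages are
validated separately on the full path.  What those runs demonstrate is
recovery of effects *under the generator's assumptions* — stationary
band-limited Gaussian oscillations, iid trial noise, a hard effect
onset.  Real EEG has non-stationary spectra, correlated trials, volume
conduction and drifting electrode quality; passing these tests says the
estimators and inference chain are correct, not that effect sizes of
real recordings are matched.

## Preprocessing

Fixed order: resample 500→250 Hz (polyphase) → zero-phase Butterworth
band-pass [1, 40] Hz (4 poles per edge; the upper analysis band ends at
40 Hz and 250 Hz sampling leaves no content above Nyquist worth
keeping) → extraction of [−10, 0) s pre-brake trials → artifact
rejection → ICA blink removal → grouping into 12 non-overlapping 5-min
epochs by brake time (`epoch = floor(t/300 s)`).

Artifact rejection is a documented threshold stand-in for toolbox-specific
automatic rejection: a trial-channel is flagged when |amplitude| >
150 µV or its 30–100 Hz power exceeds 5× the trial-set median for that
channel; ≤ 3 flagged channels are replaced by the mean of clean
channels (channel-location-aware interpolation is out of scope),
otherwise the trial is dropped.  Whole-trial dropping without
interpolation is available (`drop_only`).  Blink removal runs FastICA
(fixed seed, components = channels) on the concatenated trials and
zeroes components whose |correlation| with the mean Fp1/Fp2 signal
exceeds 0.8 *and* whose spectral power is concentrated (> 50 %) below
4 Hz; failure to converge returns the input unchanged with a warning
flag.

## Spectral and connectivity features

Band PSD per trial and channel is the plain double sum of Hann-tapered
STFT power over segments and in-band bins.  Defaults: 1-s window, 50 %
overlap (1 Hz resolution — the coarsest that still resolves the 1–4 Hz
delta band — and 19 segments per 10-s trial).  The spectrogram is
scaled so that summing over all bins returns the windowed segment
energy (Parseval); band edges are half-open `[low, high)` so the five
bands partition [1, 40) Hz without double counting.  Absolute, not
relative, power is reported.

wPLI pools the imaginary cross-spectrum over the trial's STFT segments
× in-band bins: `|Σ Im Z| / Σ |Im Z|` (standard, non-debiased
estimator; fewer than 8 segments is rejected as unstable).  Pairs with
identically zero imaginary part (zero-lag coupling) map to 0 —
treating purely instantaneous coupling as a non-connection is the
conservative choice against volume conduction.

Each 19×19 wPLI matrix is binarized at proportional sparsity ratios
0.10–0.40 in steps of 0.01 (retain the top `ceil(ratio·171)` edges).
Ties at the cut are broken lexicographically by (i, j) for
reproducibility; a `ties="all"` mode retains every tied edge instead.
Nodal degree, betweenness, efficiency and clustering coefficient are
computed on the binary graphs (the published formulas are the
binary-graph forms).  Betweenness uses the published normalization
2/(n(n−1)); the conventional 2/((n−1)(n−2)) is available via
`normalization="conventional"`.  Shortest-path lengths and counts come
from adjacency powers (a walk as long as the distance is necessarily a
shortest path), which vectorizes across the 31-ratio grid — the
pipeline evaluates on the order of 10⁵ small graphs per cohort.  Each
metric is summarized per node and band as the trapezoidal AUC over the
ratio grid (rectangular vs trapezoidal summation differs only by terms
that cancel in condition contrasts); a single-ratio grid yields a
zero-width AUC of 0 by default or an error, per configuration.

## Statistics

Per-trial metric values are averaged within epochs, then divided by the
same subject/condition/channel/band/metric's baseline-epoch value
(epoch 5, [25–30] min).  The stats stage always enumerates the full
5 metrics × 5 bands × 19 channels = 475 candidate grid; triples with
fewer than 3 paired observations are reported with a skip reason rather
than silently dropped.

Condition contrasts pair the sessions within (subject, epoch) over the
analysis window (default epochs 6–8, [30–45] min).  A Shapiro–Wilk test
on the paired differences at α = 0.05 gates between the paired t-test
and the Wilcoxon signed-rank test (identical vectors short-circuit to
statistic 0, p = 1).  Benjamini–Hochberg FDR is applied at α = 0.05 per
family, a family being the 19 channels of one (metric, band) pair; an
option pools families differently.  Reaction-time epoch means are
standardized piecewise (epochs after onset by epoch 5, earlier epochs
by epoch 0), contrasted by a paired t-test pooled over subjects ×
window epochs (30 subjects × 3 epochs → df = 89, negative t when
alerting is faster), and decomposed by a two-way repeated-measures
ANOVA (condition × epoch, subject as blocking factor).

**Known property of the pooled contrast.** Because every window epoch of
a subject is divided by the same noisy baseline epoch, the pooled
pairs are positively correlated (ρ = σ₀²/(σ₀² + σₑ²)) and the pooled
paired t is anticonservative under the null — with equal per-epoch
trial counts, about 12 % rejections at nominal α = 0.05 in simulation.
This is inherent to the analysis design, not to the implementation.
`rt_contrast(pooling="subjects")` averages the window epochs within
subject first (df = n−1) and is exactly calibrated; the calibration
tests use it, while the pooled default reproduces the published df.

The RT–metric correlation is Pearson's r between standardized RT and
standardized metric pooled over subjects × conditions × window epochs,
FDR-corrected across the 19 channels per metric.  Participant screening
(`sact_exclusion`) drops a subject only when Fisher's exact test on the
2×2 session accuracy table *and* a Welch two-sample t-test on the
session RTs are both significant at 0.05.

## Classification

Feature vectors are the standardized values of every (metric, band,
channel) triple flagged significant for the chosen band-set — either
the run's own significance table or the packaged published table (108
triples over all bands, 20 in alpha) — one sample per (subject, window
epoch, condition).  Four families are evaluated with stratified 10-fold
CV and a grid search: inverse-distance-weighted Euclidean kNN
(k ∈ 1..10), linear SVM and RBF SVM (C ∈ {0.1, 1, 5, 10, 20, 50,
100}), and XGBoost (γ = 1, learning rate 0.1, λ ∈ 1..10; 100 trees of
depth 3, no subsampling — unstated settings chosen as common defaults
and configurable).  Features are z-scored with training-fold statistics
only; the RBF width is γ = 1/(N·σ²) with σ² the pooled variance of the
scaled training-fold matrix (per-feature pooling available).
Hyperparameters are selected on the same folds used for reporting
(the optimistic reading of the published procedure); accuracy is
reported as fold mean ± standard error.

**Known property of plain folds.** Rows of one (subject, condition)
session share that session's baseline divisor, so with plain stratified
folds a classifier can match a held-out row to its session-mates in
training and read off the label: a zero-effect cohort classifies at
~80–90 % purely through this session fingerprint (measured in the
tests).  `subject_grouped=True` confines each subject to one fold and
restores chance on null data; the default remains plain folds to match
the published setup, and the battery's absolute accuracies should be
read accordingly.

## Reduced problem sizes

Default test and acceptance runs use: replicate cohorts of 30 subjects
(PSD metrics, 125 Hz trial-window synthesis, 2 window trials and 8
baseline trials per epoch) for parameter recovery; 8–12-subject
full-metric cohorts for the classifier battery; the full-rate
continuous path (500→250 Hz, artifacts on, ICA) on 2-subject, 10-minute
smoke sessions.  These sizes are the package's chosen defaults for its
own verification runs; every stage accepts full-scale input.

## Known limitations

* The artifact-rejection stage is a generic threshold/interpolation
  procedure, not a reimplementation of any specific published artifact
  pipeline.
* Graph metrics are binary-graph nodal metrics only; weighted variants
  and global network summaries are out of scope.
* The generator has no biophysical forward model: channel covariance
  beyond the single shared alpha source, scalp topography, and real
  artifact morphology are not emulated.
* The pooled RT/metric contrast and plain-fold CV inherit the
  anticonservativeness/leakage properties described above; both have
  calibrated alternatives exposed via configuration.
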