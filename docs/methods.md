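# Methods

## Problem setting

The package classifies long-term (chronic) stress from short
resting-state EEG recordings made with a five-channel consumer headset
(AF3, AF4, T7, T8, Pz; 128 Hz; ~180 s; eyes closed; no stress-inducing
task). The working hypothesis is hemispheric lateralisation: chronic
stress is associated with relatively more right- than left-hemisphere
alpha-band power, so the normalised right-minus-left alpha differences
at the frontal (AF3/AF4) and temporal (T7/T8) electrode pairs — and
their sum, the alpha asymmetry `αa` — are candidate biomarkers.

Two ground-truth definitions coexist and are both supported. The
questionnaire route thresholds the Perceived Stress Scale total score
(PSS-10, integer 0–40): with `μ` and `σ` the mean and standard deviation
of the cohort's own scores, participants below `μ − σ/2` are control,
above `μ + σ/2` stress, and the middle band is neutral and excluded
from classification. The expert route uses a psychologist's A/B/X
assignment made from a symptom interview plus the score; it has no
computational definition and is always ingested as data. On the packaged
33-participant reference table the threshold rule yields 9 control / 12
stress / 12 neutral, the expert labels 10 / 10 / 13, and the two
columns disagree for 15 participants.

## Spectral features

The PSD of each channel is estimated with Welch's method: 128-sample
segments (1 s → 1 Hz bins), Hann window, 50 % overlap, constant detrend
per segment. The window function is a convention choice (the protocol
leaves it open); Hann is the dominant default and is recorded in the
call signature so results are reproducible.

A band power is the one-sided density summed over bins with
`low ≤ f ≤ high` — inclusive at both edges on the 1 Hz grid — times the
bin width, i.e. integrated power in µV². Bands overlap by design
(slow 4–13 spans theta and alpha; gamma 25–43 shares 25–30 with beta)
and each is integrated independently. Integrated power, rather than mean
density over the band, is used throughout; the choice only rescales
features per band and cancels entirely in the asymmetry ratios and in
the t-test screening.

Relative gamma is the ratio of gamma to slow-rhythm power
(`rg = γ/slow`), the direction in which the quantity is used as a
stress biomarker in the literature; the reciprocal is available via a
flag because the opposite reading also circulates.

Features are computed once over the whole recording — one value per
participant — with an optional non-overlapping-epoch mode (features per
epoch, then averaged) for variance studies.

One 45-element vector per recording: 8 per-channel values × 5 channels
(channel order AF3, T7, Pz, T8, AF4; band order δ, θ, slow, α, βl, β,
γ, rg) followed by `αt, αf, βt, βf, αa`.

Numerical notes: `αa = αf + αt` holds exactly by construction; each
pair index is in (−1, 1) for positive powers; nonpositive alpha/beta
power raises rather than silently producing ±1; a zero `slow` power
makes relative gamma undefined and raises.

## Preprocessing

The only default preprocessing step is subtracting each channel's mean
over the whole recording (one scalar per channel — the DC offset of
dry-electrode hardware). The hardware's analogue response (1–43 Hz)
already excludes mains interference, so no filter is applied by
default; an optional 1–43 Hz zero-phase Butterworth band-pass exists
for recordings from other devices. Artifact correction (blinks, EMG) is
out of scope: the acquisition protocol controls it behaviourally
(eyes closed, still posture). Offset removal is idempotent and, because
the Welch estimator detrends each segment, leaves every band power
unchanged.

## Labeling thresholds

`σ` in the threshold rule uses the population formula (divisor *n*) by
default: applied to the 33 packaged scores it gives cut points
17.287 / 23.440, matching the published 17.33 / 23.47 to rounding (the
published values come from pre-rounded `μ = 20.4, σ = 6.14`; the
module reports full precision and does not round to match). The sample
formula (divisor *n* − 1) is available via `ddof=1`. Scores exactly on
a cut point are neutral — the rule is strict on both sides.

## Screening

Each of the 45 features is tested with a classic pooled-variance
two-sample t-test (df = n₁ + n₂ − 2), two-sided, α = 0.05; Welch's
unequal-variance variant is available via `equal_var=False`. No
multiple-testing correction is applied to the selection — the protocol
treats each feature's p-value as its own readout — but a
Benjamini–Hochberg adjusted column is included in the report as
supplementary output. Degenerate inputs (both groups constant and
equal) return t = 0, p = 1 rather than NaN. The screening's type-I
error calibration (rejection rate 0.05 under the null) and its power
against the planted lateralisation effect are verified by simulation in
the acceptance tests.

## Classification protocol

Five classifier families with small hyperparameter grids (none are
prescribed by the protocol, so the grids are package defaults, recorded
in `DEFAULT_GRIDS`):

| family | grid |
|---|---|
| SVM | kernel {linear, rbf}; C {0.1, 1, 10, 100}; γ {scale, 0.01, 0.1} |
| NB  | Gaussian likelihood, no grid |
| KNN | k {1, 3, 5, 7}, Euclidean distance |
| LR  | C {0.01, 0.1, 1, 10} (L2) |
| MLP | one hidden layer {4, 8, 16}, logistic activation, LBFGS |

Design choices where the protocol is silent:

* **Stratified folds.** With ~20 samples in 10 folds, unstratified
  splits risk single-class test folds; stratification is the default
  (an unstratified flag exists).
* **Nested grid search.** Hyperparameters are chosen by an inner
  3-fold stratified search on each outer training partition only, so
  test folds never influence model selection; a non-nested variant
  (one search on the full data, then fixed parameters) is available
  behind a flag for protocol comparison and is knowingly optimistic.
* **Pooled metrics.** Every sample is predicted exactly once across the
  outer folds and metrics are computed from the pooled predictions;
  the per-fold mean accuracy is reported alongside.
* **Scaling.** Features are z-scaled inside each fold using
  training-fold statistics only.
* **RMAE** is read as the root-mean-square probability error, the
  standard companion of the mean absolute probability error in the
  toolchains that report this metric pair; both use
  `1 − p(true class)` per sample.
* **F-measure** is support-weighted across the two classes; the
  positive-class F1 is reported alongside.

Determinism: all shuffling and all stochastic learners derive from the
single `CVConfig.seed`, so identical inputs and seeds give identical
reports.

## Synthetic cohorts

The generator exists because no recordings for this protocol are
publicly available. Each channel is the sum of

* a DC offset drawn uniformly from 4100–4300 µV (dry-electrode scale);
* 1/f^k background noise (k = 1 by default, scale 3 µV RMS), produced
  by spectrally shaping white Gaussian noise;
* one oscillation per generation band (delta, theta, alpha, beta,
  gamma — the overlapping analysis bands slow/low-beta are derived, not
  planted), realised as white noise band-passed with a 4th-order
  zero-phase Butterworth filter and scaled so a planted amplitude A
  yields band variance A²/2, the same as a sinusoid of amplitude A. A
  pure-sinusoid mode (carriers at band centres, e.g. 10 Hz for alpha)
  exists so planted powers can be checked against closed forms.

Default amplitudes (µV): delta 4, theta 3, alpha 6, beta 2, gamma 1 —
a closed-eye resting profile with dominant alpha, identical across
channels and groups. The stress contrast multiplies the AF4/T8 alpha
amplitude by `1 + alpha_lateralization_effect` (default 0.5, i.e.
×1.5). The effect magnitude is a calibration choice: the source
protocol reports only a significance level for its own (undeposited)
data, not an effect size, so the default was fixed once as a clearly
detectable but not degenerate contrast at n = 10 + 10 and is exercised
at exactly that size in the acceptance tests. PSS scores are integers
drawn from group-mean normals (control 12, stress 28, neutral 20;
SD 4), rounded and clipped to 0–40. Simulated expert labels keep the
true group with probability `1 − flip_prob` (default 0.1), otherwise
flip to neutral or the opposite group with equal probability; neutral
participants are always X. No 50 Hz line component is generated by
default (the emulated hardware's 1–43 Hz response excludes it); an
optional amplitude adds one for robustness tests.

Seeding: participant *i*'s recording uses seed `master + i`, so
enlarging a cohort never changes earlier participants; scores, expert
flips and demographics use separate streams derived from the master
seed.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: between-subject variability in band
amplitudes (within a group, subjects differ only by noise realisation,
which makes planted contrasts easier to classify than clinical ones),
eye-blink/EMG artifacts, nonstationarity over the recording, volume
conduction and channel correlation, and any genuine link between the
EEG and the PSS score beyond shared group membership.

## Problem sizes in the test suite

The simulation-based checks use sizes chosen to make their statistical
assertions sharp at reasonable cost: 10 000 simultaneous null features
for the type-I calibration (±0.01 band ≈ 4.5 binomial SDs); 100 seeded
cohorts of 10 + 10 at the full 180 s for screening power and SVM
accuracy under the planted effect; 200 short-recording cohorts for the
null-uniformity Kolmogorov–Smirnov check; 10 null cohorts of 25 + 25
(500 pooled predictions) for the chance-band check, whose ±10-point
band is 3 binomial SDs inflated for the dependence cross-validation
induces between predictions.

## Known limitations

* The expert labeling process has no computational model; only its
  statistical footprint (a noisy relabeling with a neutral escape) is
  simulated.
* Integrated band powers on an inclusive 1 Hz grid double-count shared
  edge bins of adjacent bands (e.g. 13 Hz in low-beta and beta); this
  mirrors the stated band definitions and affects no ratio or test.
* With two classes of 10 and 10-fold CV, each outer training fold loses
  exactly one sample per class; results at these sizes have high fold
  variance, which is why the package reports pooled predictions and
  seeds everything.
* The printed cohort statistics `μ = 20.4, σ = 6.14` of the reference
  table are reproduced to rounding but not digit-for-digit (the
  full-precision population σ of the packaged scores is 6.154).
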