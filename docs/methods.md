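# Methods

This note documents the models, numerical choices and limitations behind
`fatiguecast`: a pipeline that predicts momentary (state) fatigue, rated on a
1–10 visual analog scale (VAS), from passively collected wrist-wearable
biosignals, and identifies which digital biomarkers carry explanatory power.

## Problem setting

Participants wear an arm sensor for two weeks recording heart rate (HR),
inter-beat intervals (IBIs), electrodermal activity (EDA), skin temperature
and total acceleration, plus interval step counts; day-level weather is
attached externally. Several times a day they rate their momentary fatigue.
Three subgroups are modeled separately: healthy controls (CO), MS patients
with a functional autonomic nervous system (MS I, abbreviated
autonomic-symptom score ≤ 17) and MS patients with a dysfunctional ANS
(MS II, score > 17), because autonomic dysfunction plausibly changes how
biosignals relate to perceived fatigue.

## Feature extraction

Every rating is summarized over five aggregation horizons: 1 h, 3 h and 6 h
before the rating, the previous night's sleep period (`as`), and the time
since waking (`aw`). The hour windows are clipped at wake time, so a rating
less than one hour after waking makes the 1h/3h/6h and awake windows
identical, and a rating between one and three hours after waking makes
3h/6h/awake identical.

*Sleep/wake* is estimated by an actigraphy-style heuristic: a minute is
quiescent when both acceleration and HR fall below participant-adaptive
thresholds (midpoint of the channel's 20th/80th percentiles; a channel with
less than a minimal dynamic range is considered uninformative); gaps up to
20 min are closed, sub-5-min blips removed, and the longest quiescent run of
at least 3 h per noon-to-noon window becomes the night's single main sleep
period. This stand-in recovers the synthetic generator's schedules to
within ±1 min; real polysomnographic accuracy is out of scope.

*Heart-rate variability* is computed only inside 5-min rest windows on a
grid anchored at local midnight: population SD of acceleration below 0.05
(generator units; configurable — the protocol gives no number), mean HR
below 0.55·(220 − age), at least 10 beats, and fewer than 4 artifact beats.
An artifact is an IBI deviating more than 25% from the median of its up to 5
preceding accepted IBIs (a standard Malik-style rule; the original
artifact-correction reference gives no closed-form rule) and is repaired by
linear interpolation. Per cleaned window we compute SDNN (population SD of
IBIs) and the Poincaré widths SD1/SD2 (population SDs of the perpendicular
and along-line coordinates of consecutive-IBI pairs). Under the population
convention SD1 ≡ SDSD/√2 exactly, where SDSD is the population SD of
successive differences; the classical RMSSD omits the mean-centering and
coincides only approximately, which is why RMSSD is not emitted as a
separate feature.

Aggregation statistics per horizon are min/max/mean/population SD plus an
OLS slope in units/hour — over 1-min means for HR/EDA/skin temperature, and
over one value per rest window for the HRV metrics. EDA peaks are local
maxima of the phasic signal (Butterworth high-pass at 0.05 Hz where the
sampling rate permits, otherwise a 10-min rolling-minimum baseline removal)
with prominence ≥ 0.05; the "SD of peaks" feature is the population SD of
counts over full 5-min subwindows. Activity features are acceleration
stats, the trapezoidal integral of acceleration magnitude
(acceleration·hours) and the step sum with proration of intervals
straddling the horizon edge. Routine features are time of day, time awake,
previous sleep duration and the deviations of that night's bed/wake times
from the participant's study means. Weather features are day-level and
identical for all ratings of a day.

Each feature carries a group tag (CAR / EDA / ACC / WEA / ROUTINE) used by
the ablation study. Skin-temperature features are tagged EDA by default
(they share the skin-surface modality and no dedicated tag exists);
the mapping is overridable via `RunConfig.feature_groups`.

## Preprocessing

Features and the VAS rating are z-scored within each participant over the
full study, ignoring missing values, using the population (divide-by-n) SD
so small examples are exact. Zero then equals the participant's mean, and
missing values are imputed with zero. Normalization statistics are computed
once per participant over the whole study rather than per cross-validation
fold; this mirrors the modeled protocol but leaks a small amount of
information from test rows into the scaling — acceptable here because the
quantity of interest is relative within-participant variation, and flagged
for users who need strictly out-of-sample claims. Models are always trained
on complete cases; evaluation is reported both on complete cases and on all
rows with imputation.

## The additive model

The response (normalized VAS) is modeled as an intercept plus a sum of 1-D
smooth functions of single features. Each smooth is a low-rank P-spline:
cubic B-splines on uniform knots (k = 10 basis functions by default) with a
second-difference wiggliness penalty, plus a separate ridge penalty on the
wiggliness penalty's null space (the constant/linear part). This "double
penalty" lets a term shrink to exactly nothing, performing variable
selection during fitting. Terms are centered by absorbing the sum-to-zero
constraint into the basis, which also makes the intercept orthogonal to
every term, so the total effective degrees of freedom (EDF) decompose
exactly as 1 + Σ term EDFs.

Smoothing weights are selected by a REML-like criterion using extended
Fellner–Schall multiplicative updates (one Cholesky per iteration;
penalties clipped to [1e-8, 1e10] after unit-Frobenius scaling;
convergence at max |Δ log λ| < 3e-3). GCV minimized by bounded L-BFGS-B on
the log-penalties from fixed restarts is available as an option but is not
the default: under a pure-noise response GCV left individual terms at up to
~5.5 EDF in our calibration runs, while the REML-like updates (like mgcv's
REML on the same data) shrink most null terms to ~0. Repeated fits of one
design on many row subsets warm-start the updates from a full-data
reference fit, passed explicitly so each fit remains a pure function of its
inputs.

Per-term EDF is the trace of the term's block of (XᵀX + S)⁻¹XᵀX. Term
p-values are Wald tests against zero computed on the scale of the fitted
term values (not the coefficients), using the rank-r pseudo-inverse of the
Bayesian covariance of the fitted values with r = rounded EDF (at least 1),
referred to an F distribution with (r, n − EDF_total) degrees of freedom.
Testing in function space preserves power when the shrinkage penalty
concentrates a fit in heavily penalized directions; the implementation was
validated against mgcv's shrinkage smooths (`bs="ts"`, REML) on matched
data. The p-values are approximations, adequate for ranking terms during
elimination rather than for confirmatory inference.

Partial-effect curves are evaluated on a grid over the training range
(inputs clamped to that range at prediction time) and labeled by shape:
monotone rise/fall when first differences keep one sign within a 5%-of-range
slack and the total movement exceeds 0.1 (normalized-response units), arch/
dip for a single interior extremum with both limbs above the threshold,
flat otherwise (overall range below 0.05 is always flat).

## Variable selection

Backward elimination runs on complete cases. Each iteration fits the
current candidate set on `n_subsamples` subsamples (default 1000; the
source protocol itself reports both 1000 and 100, so the count is
configurable and reduced to 25–50 in the test suite, where the averaged
statistics are already stable), each excluding all rows of two randomly
chosen participants. Candidates with mean EDF < 0.1 are purged together;
otherwise the single candidate with the highest mean p > 0.05 is dropped
(ties break to the lexicographically last name, deterministically). When
neither rule fires, the model is refitted on all participants and the same
rules are re-applied on full-data fits to a fixed point — the protocol's
"once more" is ambiguous, and iterating guarantees the final model satisfies
both rules.

## Evaluation

Explained variance is defined about zero: R² = 1 − Σ(y−ŷ)²/Σy², reported in
percent. Because zero is the participant's normalized mean, the
per-participant-mean baseline regressor scores exactly R² = 0 for every
participant and dataset — the only definition consistent with a baseline
column of exact zeros. Group metrics are unweighted means over test
participants. Within-group evaluation is leave-one-participant-out with the
group's selected terms refitted per fold; across-group evaluation fits once
on the training group and scores each test participant separately,
reusing the training group's selected terms. Paired comparisons use
two-sided Wilcoxon signed-rank tests (exact for ≤ 25 pairs, normal
approximation with continuity correction above; all-zero differences give
p = 1).

The ablation study re-runs selection + LOPO under ten feature-subset
configurations: all four biosignal groups, minus each, only each, and
routine-only (routine features are always included). Significance against
routine-only uses paired Wilcoxon tests across participant perturbations:
each perturbation excludes two random participants, fits on the remaining
complete cases and scores the excluded pair; the exclusion pairs are shared
across configurations so the comparison is paired. "Perturbation" is not
defined precisely in the source protocol; this reading mirrors the
selection loop's subsampling.

## Synthetic cohorts

Real recordings of this kind are not publicly deposited, so the package
ships a generator whose defaults emulate the study conditions: three
groups, 14 rating days (streams span one extra night so every rating day
has a completed prior night), Poisson-distributed ~3.8 ratings/day drawn
uniformly over [wake + 1 h, bedtime − 5 min], and 25% incomplete feature
vectors. Missingness is injected as motion bursts covering the pre-rating
hour (85%, killing the 1-h cardiac features — the dominant real mechanism)
or EDA dropouts (15%); ratings whose pre-rating hour contains no other
rating are corrupted preferentially so the realized incomplete fraction
tracks the requested rate.

Generation is two-stage: streams are synthesized, the pipeline's own
extractor (with its own estimated sleep schedule) produces per-rating
features, and ratings are computed from a known additive model over the
*normalized extracted* features plus Gaussian noise (latent SD 0.8 by
default, chosen to land explained variance in the 20–35% regime typical of
ambulatory fatigue data). At zero noise a rating is therefore an exact
function of stored truth features, so recovery failures indicate modeling
problems, not extractor/generator mismatch. VAS values are
clip(mean_p + sd_p·latent, 1, 10) rounded to 0.1.

Channel models are deliberately minimal: AR(1) Gaussian IBIs whose marginal
SD is the SDNN target and whose lag-1 correlation 1 − (SD1/SDNN)² hits the
SD1 target (infeasible when SD1 > SDNN·√2); EDA as a tonic sinusoid plus
Poisson-timed exponential-decay conductance responses; acceleration as a
quiet floor plus bounded activity bouts; skin temperature as a slow
sinusoid; steps as Poisson counts boosted during bouts; sleep onset
~23:00 ± 0.7 h with duration 8 ± 0.8 h. Rare missed-beat artifacts double
an IBI. The default ground truth assigns each group directionally distinct
effects in the published pattern — time of day rising for CO and MS II,
time awake rising and sleep duration falling for MS I, asleep-HR rising for
MS II, parasympathetic effects with opposite signs in CO vs MS II — with
bounded effect shapes (±tanh for monotone, Gaussian bump for arch/dip).

What passing tests on this cohort do **not** show: robustness to real
sensor artifacts (motion-correlated EDA drift, detached electrodes),
physiologic circadian HRV structure, non-random missingness tied to
symptom severity, or medication effects. The generator's realism stops at
second-order statistics and the feature→rating link is additive by
construction, matching the model class — real data offer no such guarantee.

## Default problem sizes

The test suite and the acceptance script run scaled-down cohorts (5–14
days, 4–20 participants, 25–50 subsamples, 30 perturbations) — sizes at
which every averaged statistic used by the selection and evaluation loops
is already stable in our calibration runs, while a full run at the study's
own scale (74 participants, 1000 subsamples) uses the same code paths via
configuration.

## Known limitations

* Sleep/wake estimation is a transparent heuristic, not a validated
  actigraphy algorithm; the true algorithm behind the modeled protocol is
  unspecified.
* Term p-values are approximations; the elimination outcome, not individual
  p-values, is the validated quantity.
* Per-participant normalization over the full study leaks scaling
  information across CV folds (documented protocol behavior).
* The 1h/3h/6h rest-window grid is anchored at local midnight, so horizon
  windows shorter than 5 min after clipping contain no rest window by
  construction.
* Reported complete-case counts in the modeled protocol are internally
  inconsistent (2234 vs 3733 − 927 = 2806); the pipeline simply returns
  rows minus incomplete rows.
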