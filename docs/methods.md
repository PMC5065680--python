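# Methods

This note records the scientific and numerical choices behind the
package: the labeling and modeling procedure, the parameters that
matter, what the synthetic cohorts do and do not emulate, and the known
limitations.

## Timeline construction

Observations are assigned to half-open hourly bins [k, k+1) anchored at
ICU start and averaged within bins. Half-open binning makes the
assignment unambiguous; bin sums are computed in time-sorted order so
results are independent of input row ordering. When no explicit ICU
admission time is available it is approximated as 60 minutes before the
first extended-vital measurement.

Invasive (arterial-line) and noninvasive blood pressure are recorded as
separate channels; within each hour the invasive value is preferred
when that bin was actually observed, falling back to the noninvasive
source (configurable — clinical convention, since arterial lines are
the more accurate measurement when present). Pulse pressure is systolic
minus diastolic of the resolved series.

Missing bins are imputed by carry-forward after the first observed bin
and back-fill before it. This is deliberately simple and favors
comparability across prediction times over statistical efficiency; a
channel never observed during a stay is left missing and flagged rather
than fabricated, and the inclusion filters decide its fate. Imputation
is idempotent and never alters observed bins (property-tested).

Plausibility ranges (HR 10–300 /min, RR 0–80 /min, SpO2 10–100 %,
temperature 25–45 °C, systolic 20–300 mm Hg, GCS 3–15, and analogous
lab ranges) reject implausible rows at parse time with a logged reason.
Temperature may arrive in °F per a file-level flag and is normalized to
°C.

## Gold standard

Suspicion of infection is retrospective: an antibiotic administration
followed by a culture draw within 72 h, or a culture followed by an
antibiotic within 24 h; the suspicion time of a qualifying pair is its
first event, floored to the hour. The onset scan runs from up to 48 h
before suspicion (clamped to data availability) to 24 h after it
(clamped to ICU departure); the baseline is the **imputed** hourly SOFA
total at the window start, and onset is the first later in-window hour
whose total is at least baseline + 2.

When several suspicion pairs qualify, windows are evaluated in
chronological order of suspicion time and the first window yielding an
onset defines the label (configurable; only analyzing the earliest
suspicion is also supported). Rationale: a patient whose earliest
antibiotic/culture pair is unrelated to a later deterioration should
not be forced nonseptic by that accident of ordering.

SOFA subscores with absent inputs score 0 ("normal"). The respiration
subscore is a ventilation-free variant using the SpO2/FiO2 ratio with
cut-points >400→0, ≤400→1, ≤315→2, ≤235→3, ≤150→4 and room air
(FiO2 = 0.21) assumed when FiO2 is unrecorded; the table is
config-overridable since published SpO2/FiO2 adaptations differ
slightly. The cardiovascular subscore is MAP-based (0/1) because
vasopressor dosing channels are not carried; MAP falls back to
diastolic + pulse pressure / 3 when unmeasured. The renal subscore uses
creatinine only (urine-output accumulation is not implemented; the
absent-input rule covers it).

Inclusion filters run sequentially, mirroring a study flow diagram:
age < 15; no measurements; any of the 8 predictors never recorded;
septic onset outside [7, 500] h; optionally any pre-ICU antibiotic
administration. Labels are always computed on the full data before any
deletion experiment, so they are invariant under dropout.

## Features

For prediction hour t, x₁ is the bin covering (t−1, t] and x₂ the bin
covering (t−2, t−1]; only these two hours of data are needed at
prediction time. Age enters the x₁ block only (a Δage feature would be
identically zero).

Posterior-probability maps shrink empirical per-bin class rates toward
the training prevalence π:

    posterior = (n₁ + α·π) / (n + α)

with α = 10 for both the 1-D maps (20 quantile bins) and the 2-/3-way
delta tables (5 quantile bins per variable). Shrinkage keeps empty
cells well-defined (an unvisited cell evaluates exactly to π) and
tames noisy tail bins; quantile (equal-mass) binning is robust to the
heavy tails of vital-sign distributions. 1-D maps interpolate linearly
between bin centers with constant extrapolation, so the feature is
continuous in its input; tables are piecewise constant. All pairs
(21) and triples (35) of the 7 dynamic predictors are tabulated by
default; the combination list, bin counts and α are configuration.

The x₁/x₂ blocks are z-scored with training statistics because
elastic-net penalties are scale-sensitive. Every fitted statistic —
edges, posteriors, standardization — derives from training-fold rows
only, enforced structurally by fitting the featurizer inside the
classifier's `fit`.

Sampling times: septic stays are sampled at onset − horizon (the ≥7-h
onset rule guarantees a full two-hour history); nonseptic stays at a
seeded uniform random hour in [max(2, 7 − horizon), n_hours]. Nonseptic
hours are redrawn per partitioning.

## Classifier and experiment design

The classifier is logistic regression with an elastic-net penalty
(sparsity-inducing) and class weights inverse to class frequency, so
sensitivity and specificity are valued equally at the default
operating point. Hyperparameters are chosen by inner 3-fold stratified
CV scored by AUROC over mixing ratios {0.1, 0.5, 0.9} × 20 log-spaced
penalty strengths (10⁻³–10²). For large sweeps (horizon and dropout
grids) the package also supports a fixed setting (C = 1, l1_ratio =
0.5, `tune=False`), which we use in the degradation experiments where
the quantity of interest is a trend rather than a single best score.

The main experiment is 4-fold cross-validation repeated over 4
independent random partitionings and 5 prediction horizons (0–4 h).
Folds are stratified by class so every fold carries both classes at
realistic prevalence; assignments are seeded (partition seed = base
seed + partition index) and bit-reproducible. One feature row per stay
per horizon matches the per-stay classification framing; per-hour risk
scoring is available separately (`predict_risk`) for deployment-style
use.

The deletion experiment thins the raw observation streams of the
bedside channels: the first observation of each channel per stay is
always retained, later ones are deleted independently with probability
P ∈ {0, .1, .2, .4, .6}; timelines are then rebuilt and re-imputed
while labels stay fixed from the full data. At P = 0 the pipeline is
bit-identical to the untouched path (asserted in tests).

## Evaluation

AUROC is trapezoidal (equivalent to pairwise concordance, ties counted
half — verified against a brute-force oracle to 1e−12); APR is average
precision (step-sum, no PR-space interpolation). Operating thresholds
are chosen to bring sensitivity closest to 0.80, with ties broken
toward higher specificity and then the lower threshold. DOR = LR+/LR−
holds by construction and is re-verified on random confusion matrices;
infinite ratios (empty error cells) are flagged and excluded from
averages. Comparator scores are reported as pooled single values over
the cohort, and classifier-vs-comparator comparisons are one-sample
two-sided t-tests of the per-fold values against the pooled constant,
with an exact-comparison fallback at zero variance.

## Synthetic cohorts

The generator emulates the features of real ICU streams the pipeline
actually depends on: per-channel Poisson observation cadences near
real-world per-hour medians (HR/RR/SpO2 ≈ 1.06/h, noninvasive BP ≈
0.88/h, temperature ≈ 0.27/h, GCS ≈ 0.25/h, invasive BP in 43% of
stays), autocorrelated (mean-reverting Ornstein-Uhlenbeck) vitals so
that two-hour windows and deltas are informative (white noise would
make Δx features meaningless), length of stay with median ≈ 2 days and
a long tail, age median ≈ 65, and sepsis prevalence 11.3% by
independent Bernoulli assignment.

Designed-septic stays receive a gradual pre-onset deterioration ramp
(6–12 h, reaching a per-channel fraction of the full effect chosen to
stay below the +2 SOFA threshold) followed by a full-effect step at the
designed onset hour: full effects HR +28 /min, RR +9 /min, temperature
+1.3 °C, SpO2 −17 %, systolic −32 mm Hg, diastolic −22 mm Hg, GCS −4.
The step is accompanied by a complete vitals assessment burst —
clinically, a bedside team charts a full set of observations during
acute deterioration — which is also what makes the retrospectively
recovered onset land on the designed hour. Every stay gets a complete
admission assessment in its first minutes, so the "all predictors
recorded" filter is exercised by configuration rather than by chance. A
qualifying antibiotic/culture pair is placed near the designed onset;
10% of nonseptic stays carry a lone antibiotic and 5% a lone culture as
decoys for the window logic.

What the generator does **not** emulate: real marginal distributions
beyond coarse ranges and cadence, inter-channel cross-correlations
of real physiology, nonseptic deterioration (e.g. cardiogenic shock)
that produces SOFA rises without infection, charting artifacts, or
mortality dynamics. Passing tests therefore demonstrate pipeline
correctness and internal consistency — label recovery, train/test
hygiene, monotone degradation — not clinical performance on real
patients; numbers on this synthetic cohort are systematically more
optimistic than anything achievable on real EHR data.

## Problem sizes and numerical choices

The acceptance-style experiments use cohorts of 500 stays
(label-recovery), 2000 stays (signal recovery and comparator ordering,
one partitioning, 10-value strength grid) and 800 stays (horizon and
dropout degradation, 2 partitionings with the fixed-hyperparameter
classifier); the acceptance script uses 1000 stays and 2
partitionings. These sizes give stable estimates of the tested
properties while keeping runs desk-scale.

Degenerate inputs: stays with no extended vitals raise an explicit
"empty stay" error; single-class training sets are rejected; CV folds
whose test split carries one class are skipped with a NaN row;
single-class posterior maps degenerate to the prior with a warning. A
1e−12 relative tolerance absorbs float error at exact SpO2/FiO2
threshold ratios. The saga solver runs with tol 1e−4 and max_iter
2000; occasional non-convergence at extreme penalty settings affects
only hyperparameter-grid corners.

## Limitations

* The Sepsis-3 operationalization inherits the known ambiguity of
  onset-time definitions; baseline SOFA uses the imputed value at the
  window start.
* The smoothing form, bin counts, and combination lists of the
  posterior features are package choices exposed as configuration;
  other reasonable choices exist.
* SAPS II omits variables whose channels are not carried (electrolytes,
  bicarbonate, BUN, PaO2/FiO2, chronic disease and admission type
  default to 0 points unless supplied); comparisons against it on
  vitals-only data understate its real-world value.
* No calibration assessment (discrimination only), no bootstrap or
  rank-based AUROC tests, and no septic-shock sub-classification.
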