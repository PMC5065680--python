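# sepsight

Machine-learning prediction of sepsis onset in the ICU from **minimal
bedside data**: systolic blood pressure, pulse pressure, heart rate,
respiration rate, temperature, SpO2, Glasgow Coma Score, and age —
no laboratory results required at prediction time.

The package is aimed at clinical-informatics researchers who want a
fully reproducible, end-to-end implementation of a Sepsis-3
onset-prediction pipeline that can be developed and validated without
access to restricted patient-level datasets.

## What it implements

1. **Timelines** — long-format observation tables (one timestamped
   measurement per row) are binned into hourly grids anchored at ICU
   start (half-open bins, within-bin averaging), invasive/noninvasive
   blood pressure is source-resolved, and gaps are imputed by
   carry-forward with back-fill before the first observation.
2. **Sepsis-3 gold standard** — suspicion of infection is a
   culture/antibiotic pair co-occurring within defined windows
   (antibiotics first: culture within 72 h; culture first: antibiotics
   within 24 h); onset is the first hour, within a window from 48 h
   before to 24 h after suspicion, at which the total SOFA score rises
   ≥ 2 points above its value at the window start. Absent SOFA inputs
   score 0, and the respiration subscore is a ventilation-free variant
   driven by the SpO2/FiO2 ratio. Study inclusion filters (age ≥ 15,
   all predictors recorded, onset within 7–500 h, optional pre-ICU
   antibiotic exclusion) are applied sequentially with a per-filter
   exclusion report.
3. **Features** — for a prediction hour *t*, the raw inputs are the
   predictor values of the last two hourly bins, x₁ and x₂. The
   feature vector

   ξ = [x₁, x₂, … P(s=1|x₁ⁱ) …, … P(s=1|Δxⁱ) …, … P(s=1|Δxⁱ,Δxʲ) …, … P(s=1|Δxⁱ,Δxʲ,Δxᵏ) …]

   augments them with smoothed 1-D and tabular posterior-probability
   maps over the deltas Δx = x₁ − x₂, all fitted on training folds
   only (default width 86).
4. **Classifier** — elastic-net-penalized logistic regression with
   balanced class weights, wrapped as a scikit-learn estimator
   (`InsightClassifier`) whose `fit` also fits the featurizer, so the
   whole model composes with sklearn model selection.
5. **Evaluation** — AUROC/APR, operating points at a target
   sensitivity of 0.80 (with F1, DOR, LR+, LR−, accuracy), one-sample
   t-comparisons of per-fold metrics against pooled comparator scores
   (qSOFA, SIRS, MEWS hourly; SOFA and SAPS II at admission), and a
   robustness experiment that deletes raw observations uniformly at
   random (P ∈ {0, .1, .2, .4, .6}, first measurement of each channel
   always retained, gold standard fixed from the full data).
6. **Synthetic cohorts** — a generator of ICU stays with
   mean-reverting vital-sign processes at realistic per-channel
   observation cadences, culture/antibiotic events, and SOFA-visible
   deterioration for designed-septic stays at a configurable
   prevalence (default 11.3%).

## Worked example

```python
from sepsight import (SynthConfig, generate_cohort, prepare_cohort,
                      ExperimentPlan, run_cv_experiment)

cohort, truth = generate_cohort(SynthConfig(n_stays=600, seed=2))
timelines, labels, included, report = prepare_cohort(cohort)
print(sum(labels[s].is_septic for s in included), "septic of", len(included))

plan = ExperimentPlan(n_partitionings=1, horizons=(0, 4), base_seed=3,
                      classifier_params={"tune": False})
results, scores = run_cv_experiment(timelines, labels, included, plan)
print(results.groupby("horizon")[["auroc", "apr"]].mean())
```

prints (from an actual run):

```
60 septic of 600
            auroc       apr
horizon
0        0.999506  0.995886
4        0.858025  0.564075
```

i.e. 60 of the 600 generated stays (10%) were labeled septic by the
retrospective Sepsis-3 rule, the cross-validated classifier separates
septic from nonseptic stays nearly perfectly at the hour of onset
(AUROC 0.9995), and discrimination degrades when predicting four hours
ahead of onset (AUROC 0.858) because only the early part of the
pre-onset physiological deterioration is visible.

The same pipeline is available from the shell:

```bash
sepsight run-all --n 500 --seed 7 --out-dir runs/demo
sepsight dropout --data-dir runs/demo/data --out-dir runs/demo --fast
```

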