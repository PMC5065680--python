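"""Elastic-net classifier and the cross-validated multi-horizon experiment.

The classifier is a penalized logistic regression (elastic-net penalty,
which induces sparsity among the feature weights) stacked on the
posterior-probability featurizer.  Training rows are one per stay per
horizon: septic stays sampled at onset minus horizon, nonseptic stays at
a seeded random hour.  The experiment repeats 4-fold cross-validation
over independent random partitionings of the cohort and over prediction
horizons of 0-4 hours; every fitted object (featurizer statistics,
posterior maps, weights, hyperparameters) depends only on the training
folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .features import InsightFeaturizer, build_raw_matrix, select_sample_time
from .labels import SepsisLabel
from .timeline import StayTimeline


class InsightClassifier(ClassifierMixin, BaseEstimator):
    """Posterior-feature construction plus elastic-net logistic regression.

    ``fit`` expects the raw (n, 15) two-hour-window matrix produced by
    :func:`sepsight.features.build_raw_matrix`; the featurizer is fitted
    inside ``fit`` so no test-fold row can leak into the feature maps.
    Classes are weighted inversely to frequency so sensitivity and
    specificity are valued equally.

    Parameters
    ----------
    tune : bool
        If True (default), choose penalty strength and mixing by inner
        stratified cross-validation over ``l1_ratios`` x ``n_Cs``
        log-spaced strengths, scored by AUROC.  If False, fit once at
        ``C``/``l1_ratio`` (much faster; used for large sweeps).
    """

    def __init__(
        self,
        n_bins_1d=20,
        bins_per_var=5,
        alpha=10.0,
        pairs="all",
        triples="all",
        tune=True,
        l1_ratios=(0.1, 0.5, 0.9),
        n_Cs=20,
        inner_cv=3,
        C=1.0,
        l1_ratio=0.5,
        max_iter=2000,
        tol=1e-4,
        random_state=None,
    ):
        self.n_bins_1d = n_bins_1d
        self.bins_per_var = bins_per_var
        self.alpha = alpha
        self.pairs = pairs
        self.triples = triples
        self.tune = tune
        self.l1_ratios = l1_ratios
        self.n_Cs = n_Cs
        self.inner_cv = inner_cv
        self.C = C
        self.l1_ratio = l1_ratio
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, int)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training data contain a single class")
        self.featurizer_ = InsightFeaturizer(
            n_bins_1d=self.n_bins_1d,
            bins_per_var=self.bins_per_var,
            alpha=self.alpha,
            pairs=self.pairs,
            triples=self.triples,
        ).fit(X, y)
        Xf = self.featurizer_.transform(X)
        common = dict(
            solver="saga",
            class_weight="balanced",
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=self.random_state,
        )
        if self.tune:
            cv = StratifiedKFold(
                n_splits=self.inner_cv, shuffle=True, random_state=self.random_state
            )
            est = LogisticRegressionCV(
                Cs=np.logspace(-3, 2, self.n_Cs),
                l1_ratios=list(self.l1_ratios),
                cv=cv,
                scoring="roc_auc",
                n_jobs=1,
                use_legacy_attributes=False,
                **common,
            ).fit(Xf, y)
            self.C_ = float(np.atleast_1d(est.C_)[0])
            self.l1_ratio_ = float(np.atleast_1d(est.l1_ratio_)[0])
        else:
            est = LogisticRegression(C=self.C, l1_ratio=self.l1_ratio, **common).fit(Xf, y)
            self.C_ = self.C
            self.l1_ratio_ = self.l1_ratio
        self.estimator_ = est
        self.coef_ = est.coef_
        self.intercept_ = est.intercept_
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.decision_function(self.featurizer_.transform(np.asarray(X, float)))

    def predict_proba(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict_proba(self.featurizer_.transform(np.asarray(X, float)))

    def predict_risk(self, X):
        """Sepsis risk score in (0, 1) for raw two-hour-window rows."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return self.estimator_.predict(self.featurizer_.transform(np.asarray(X, float)))


@dataclass
class ExperimentPlan:
    """Cross-validation design: partitionings x folds x horizons."""

    n_partitionings: int = 4
    n_folds: int = 4
    horizons: tuple[int, ...] = (0, 1, 2, 3, 4)
    base_seed: int = 0
    classifier_params: dict = field(default_factory=dict)


def sample_times(
    labels: dict[object, SepsisLabel],
    timelines: dict[object, StayTimeline],
    stay_ids,
    horizon: int,
    rng: np.random.Generator,
) -> dict[object, int]:
    """One prediction hour per stay at the given horizon."""
    return {
        sid: select_sample_time(labels[sid], horizon, timelines[sid].n_hours, rng)
        for sid in stay_ids
    }


def run_cv_experiment(
    timelines: dict[object, StayTimeline],
    labels: dict[object, SepsisLabel],
    included_ids: list,
    plan: ExperimentPlan,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full partitionings x folds x horizons experiment.

    Returns (fold results, per-sample test scores).  Fold results carry
    one row per (partitioning, fold, horizon) with test AUROC and APR;
    folds whose test split holds a single class are skipped with a
    warning row (NaN metrics).  Nonseptic sampling hours are redrawn per
    partitioning, seeded from the plan.
    """
    stay_ids = np.asarray(list(included_ids))
    y = np.array([int(labels[sid].is_septic) for sid in stay_ids])
    rows, score_rows = [], []
    for p in range(plan.n_partitionings):
        seed = plan.base_seed + p
        skf = StratifiedKFold(n_splits=plan.n_folds, shuffle=True, random_state=seed)
        splits = list(skf.split(stay_ids, y))
        for horizon in plan.horizons:
            rng = np.random.default_rng([plan.base_seed, p, horizon])
            times = sample_times(labels, timelines, stay_ids, horizon, rng)
            X = build_raw_matrix(timelines, times, stay_ids)
            for k, (train, test) in enumerate(splits):
                if len(np.unique(y[test])) < 2 or len(np.unique(y[train])) < 2:
                    rows.append(
                        dict(partitioning=p, fold=k, horizon=horizon, auroc=np.nan,
                             apr=np.nan, n_test=len(test), n_pos=int(y[test].sum()))
                    )
                    continue
                clf = InsightClassifier(random_state=seed, **plan.classifier_params)
                clf.fit(X[train], y[train])
                scores = clf.predict_risk(X[test])
                rows.append(
                    dict(
                        partitioning=p,
                        fold=k,
                        horizon=horizon,
                        auroc=roc_auc_score(y[test], scores),
                        apr=average_precision_score(y[test], scores),
                        n_test=len(test),
                        n_pos=int(y[test].sum()),
                        C=clf.C_,
                        l1_ratio=clf.l1_ratio_,
                    )
                )
                score_rows.append(
                    pd.DataFrame(
                        {
                            "partitioning": p,
                            "fold": k,
                            "horizon": horizon,
                            "stay_id": stay_ids[test],
                            "t": [times[sid] for sid in stay_ids[test]],
                            "score": scores,
                            "label": y[test],
                        }
                    )
                )
    results = pd.DataFrame(rows)
    scores_df = (
        pd.concat(score_rows, ignore_index=True)
        if score_rows
        else pd.DataFrame(columns=["partitioning", "fold", "horizon", "stay_id", "t", "score", "label"])
    )
    return results, scores_df
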