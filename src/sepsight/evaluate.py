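"""Discrimination metrics, fixed-sensitivity operating points, score
comparisons, and the random observation-deletion robustness experiment.

AUROC is the trapezoidal area under the ROC curve (equivalent, with tie
handling, to the pairwise concordance statistic); APR is the average
precision — the sum of precision at each achieved recall step, with no
linear interpolation in PR space.  Operating points are chosen so the
sensitivity is closest to a target (0.80 by default), and diagnostic
odds ratio and likelihood ratios are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from .channels import EXTENDED_VITALS


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """Trapezoidal AUROC plus the ROC step curve."""
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined: a single class is present")
    fpr, tpr, thr = roc_curve(labels, scores)
    return float(roc_auc_score(labels, scores)), pd.DataFrame(
        {"fpr": fpr, "tpr": tpr, "threshold": thr}
    )


def pr_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """Average precision (step-sum) plus the precision-recall curve."""
    labels = np.asarray(labels, int)
    if labels.sum() == 0:
        raise ValueError("APR undefined: no positive labels")
    prec, rec, thr = precision_recall_curve(labels, scores)
    curve = pd.DataFrame({"recall": rec[:-1], "precision": prec[:-1], "threshold": thr})
    return float(average_precision_score(labels, scores)), curve


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    f1: float
    dor: float
    lr_plus: float
    lr_minus: float
    accuracy: float
    tp: int
    fn: int
    fp: int
    tn: int
    infinite: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def confusion_metrics(tp: int, fn: int, fp: int, tn: int, threshold: float = np.nan) -> OperatingPoint:
    """All operating-point metrics from one confusion matrix.

    Ratios with a zero denominator are reported as inf and flagged.
    """
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        lr_plus = sens / (1 - spec) if spec < 1 else np.inf
        lr_minus = (1 - sens) / spec if spec > 0 else np.inf
        dor = (tp * tn) / (fp * fn) if fp * fn > 0 else np.inf
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else np.nan
    acc = (tp + tn) / (tp + tn + fp + fn)
    infinite = not (np.isfinite(dor) and np.isfinite(lr_plus) and np.isfinite(lr_minus))
    return OperatingPoint(
        threshold=threshold, sensitivity=sens, specificity=spec, f1=f1, dor=dor,
        lr_plus=lr_plus, lr_minus=lr_minus, accuracy=acc, tp=tp, fn=fn, fp=fp, tn=tn,
        infinite=infinite,
    )


def operating_metrics(scores, labels, target_sensitivity: float = 0.80) -> OperatingPoint:
    """Operating point whose sensitivity is closest to the target.

    Predictions are positive at score >= threshold, thresholds taken from
    the unique scores.  Ties on |sensitivity - target| break toward
    higher specificity, then toward the lower threshold.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise ValueError("operating point undefined: a single class is present")
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best = None
    for thr in np.unique(scores):
        pred = scores >= thr
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        sens = tp / n_pos
        spec = (n_neg - fp) / n_neg
        key = (abs(sens - target_sensitivity), -spec, thr)
        if best is None or key < best[0]:
            best = (key, thr, tp, fp)
    _, thr, tp, fp = best
    return confusion_metrics(tp, int(n_pos - tp), fp, int(n_neg - fp), threshold=float(thr))


def compare_to_benchmark(fold_values, benchmark_value: float) -> dict:
    """One-sample two-sided t-test of per-fold values against a constant.

    Reports the fold mean and SD in the usual "mean (SD)" style; with
    zero variance the test degenerates to an exact comparison.
    """
    vals = np.asarray(fold_values, float)
    if len(vals) < 2:
        raise ValueError("need at least two fold values")
    mean, sd = float(vals.mean()), float(vals.std(ddof=1))
    if sd == 0.0:
        p = 1.0 if mean == benchmark_value else 0.0
    else:
        p = float(stats.ttest_1samp(vals, benchmark_value).pvalue)
    return {
        "mean": mean,
        "sd": sd,
        "benchmark": float(benchmark_value),
        "direction": "above" if mean > benchmark_value else "below",
        "p_value": p,
    }


@dataclass
class DropoutConfig:
    """Random observation-deletion settings.

    Each observation after the first of its channel within a stay is
    deleted independently with probability ``p``; the first observation
    of every channel in every stay is always retained.  Only the listed
    bedside measurement channels are thinned.
    """

    p: float = 0.0
    seed: int = 0
    channels: tuple[str, ...] = EXTENDED_VITALS

    def __post_init__(self):
        if not 0.0 <= self.p < 1.0:
            raise ValueError("deletion probability must be in [0, 1)")


def random_dropout(observations: pd.DataFrame, config: DropoutConfig) -> pd.DataFrame:
    """Thin a raw observation table by random deletion.

    Operates on raw (pre-binning) events; rows of channels outside the
    configured list are untouched.  The result is independent of the
    input row ordering.
    """
    keys = [c for c in ("stay_id", "channel", "time_h") if c in observations.columns]
    obs = observations.sort_values(keys, kind="mergesort").reset_index(drop=True)
    if config.p == 0.0:
        return obs
    rng = np.random.default_rng(config.seed)
    affected = obs["channel"].isin(config.channels).to_numpy()
    group_keys = [k for k in keys if k != "time_h"]
    is_first = ~obs.duplicated(group_keys).to_numpy()
    keep = rng.random(len(obs)) >= config.p
    keep = keep | is_first | ~affected
    return obs.loc[keep].reset_index(drop=True)


def run_dropout_experiment(
    stays: dict,
    labels: dict,
    included_ids: list,
    plan,
    p_grid=(0.0, 0.1, 0.2, 0.4, 0.6),
    horizons=(0, 1, 2, 4),
    dropout_seed: int = 0,
    timeline_config=None,
) -> dict[float, pd.DataFrame]:
    """Re-run the CV experiment on data thinned at each deletion probability.

    The gold-standard labels are determined from the full dataset and
    held fixed across all deletion levels; only the observation streams
    feeding timeline construction (and hence the features) are thinned
    and re-imputed.  At p = 0 the pipeline is byte-identical to the
    no-deletion path.
    """
    from dataclasses import replace

    from .model import run_cv_experiment
    from .timeline import build_stay_timeline

    plan = replace(plan, horizons=tuple(horizons))
    results: dict[float, pd.DataFrame] = {}
    for j, p in enumerate(p_grid):
        timelines = {}
        for idx, sid in enumerate(included_ids):
            # independent deletion stream per stay, reproducible per grid point
            cfg = DropoutConfig(p=p, seed=(dropout_seed + j, idx))
            stay = stays[sid]
            thinned = random_dropout(stay.observations, cfg)
            stay_thinned = replace(stay, observations=thinned)
            timelines[sid] = build_stay_timeline(stay_thinned, timeline_config)
        res, _ = run_cv_experiment(timelines, labels, included_ids, plan)
        results[p] = res
    return results


def pooled_comparator_metrics(
    timelines: dict,
    labels: dict,
    included_ids: list,
    score_name: str,
    horizon: int = 0,
    seed: int = 0,
) -> dict:
    """Pooled AUROC/APR of a severity score over the whole cohort.

    qSOFA/SIRS/MEWS are evaluated at the same prediction hours the
    classifier would use (onset minus horizon for septic stays, a seeded
    random hour otherwise); SOFA and SAPS II are computed at admission.
    """
    from .comparators import saps2_at_admission, score_at_hour, sofa_at_admission
    from .features import select_sample_time

    rng = np.random.default_rng(seed)
    values, y = [], []
    for sid in included_ids:
        tl = timelines[sid]
        if score_name == "sofa":
            v = sofa_at_admission(tl)
        elif score_name == "saps2":
            v = saps2_at_admission(tl)
        else:
            t = select_sample_time(labels[sid], horizon, tl.n_hours, rng)
            v = score_at_hour(tl, score_name, t - 1)
        values.append(v)
        y.append(int(labels[sid].is_septic))
    auroc, _ = roc_auc(values, y)
    apr, _ = pr_auc(values, y)
    return {"score": score_name, "auroc": auroc, "apr": apr, "n": len(y)}
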