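"""Feature construction: two-hour vitals windows and posterior-probability maps.

The classifier sees, for each stay and prediction hour t, the predictor
values of the last two hourly bins (x1 over (t-1, t], x2 over (t-2, t-1])
together with learned approximations of the posterior probability of
sepsis given those values:

* smoothed 1-D maps P(s=1 | x1_i) for each of the 8 predictors and
  P(s=1 | dx_i) for each of the 7 dynamic predictors, dx = x1 - x2;
* tabular maps P(s=1 | dx_i, dx_j) and P(s=1 | dx_i, dx_j, dx_k) over
  discretised delta combinations.

All maps use quantile (equal-mass) binning of the training values and
shrink empirically counted per-bin class rates toward the training
prevalence pi with strength alpha:

    posterior = (n_pos + alpha * pi) / (n + alpha)

so an empty cell evaluates exactly to pi.  1-D maps interpolate linearly
between bin centers with constant extrapolation; tables are piecewise
constant.  Every fitted statistic (bin edges, posteriors, z-score
standardisation) derives from training rows only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .channels import DYNAMIC_PREDICTORS
from .labels import SepsisLabel
from .timeline import StayTimeline

N_DYNAMIC = len(DYNAMIC_PREDICTORS)  # 7
N_X1 = N_DYNAMIC + 1  # age appended to the x1 block only
RAW_WIDTH = N_X1 + N_DYNAMIC  # 15 raw inputs per sample


@dataclass
class PosteriorMap1D:
    """Smoothed 1-D posterior-probability map for one variable."""

    variable: str
    input_kind: str  # "level" or "delta"
    bin_edges: np.ndarray
    posterior: np.ndarray  # one probability per bin
    prior: float

    def __call__(self, x) -> np.ndarray:
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return np.interp(np.asarray(x, float), centers, self.posterior)


@dataclass
class PosteriorTable:
    """Tabular posterior map over 2 or 3 discretised delta variables."""

    combo: tuple[int, ...]
    bin_edges: list[np.ndarray]  # per variable
    table: np.ndarray
    prior: float

    def __call__(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        idx = tuple(
            _bin_index(X[:, k], self.bin_edges[k]) for k in range(len(self.combo))
        )
        return self.table[idx]


def _quantile_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-mass bin edges; duplicate quantiles are collapsed."""
    edges = np.unique(np.quantile(values, np.linspace(0.0, 1.0, n_bins + 1)))
    if len(edges) < 2:
        # all values identical: a single degenerate bin around the value
        edges = np.array([edges[0] - 0.5, edges[0] + 0.5])
    return edges


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Assign values to bins [e_k, e_{k+1}); outside values clamp to end bins."""
    return np.clip(np.searchsorted(edges, values, side="right") - 1, 0, len(edges) - 2)


def _smoothed_posterior(n_pos, n, prior: float, alpha: float):
    return (n_pos + alpha * prior) / (n + alpha)


def fit_posterior_1d(
    values: np.ndarray,
    labels: np.ndarray,
    n_bins: int = 20,
    alpha: float = 10.0,
    variable: str = "",
    input_kind: str = "level",
) -> PosteriorMap1D:
    """Fit a smoothed 1-D posterior map on training rows only."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, int)
    prior = float(labels.mean())
    edges = _quantile_edges(values, n_bins)
    nb = len(edges) - 1
    if prior in (0.0, 1.0):
        warnings.warn(
            f"single-class training data for {variable!r}: posterior map is degenerate"
        )
        return PosteriorMap1D(variable, input_kind, edges, np.full(nb, prior), prior)
    idx = _bin_index(values, edges)
    n = np.bincount(idx, minlength=nb)
    n_pos = np.bincount(idx, weights=labels, minlength=nb)
    post = _smoothed_posterior(n_pos, n, prior, alpha)
    return PosteriorMap1D(variable, input_kind, edges, post, prior)


def fit_posterior_table(
    deltas: np.ndarray,
    labels: np.ndarray,
    combo: tuple[int, ...],
    bins_per_var: int = 5,
    alpha: float = 10.0,
) -> PosteriorTable:
    """Fit a 2- or 3-way tabular posterior map on training delta rows."""
    if len(combo) not in (2, 3):
        raise ValueError("combo must contain 2 or 3 variable indices")
    deltas = np.asarray(deltas, float)
    labels = np.asarray(labels, int)
    prior = float(labels.mean())
    cols = deltas[:, list(combo)]
    edges = [_quantile_edges(cols[:, k], bins_per_var) for k in range(len(combo))]
    shape = tuple(len(e) - 1 for e in edges)
    flat_idx = np.ravel_multi_index(
        tuple(_bin_index(cols[:, k], edges[k]) for k in range(len(combo))), shape
    )
    size = int(np.prod(shape))
    n = np.bincount(flat_idx, minlength=size)
    n_pos = np.bincount(flat_idx, weights=labels, minlength=size)
    table = _smoothed_posterior(n_pos, n, prior, alpha).reshape(shape)
    return PosteriorTable(tuple(combo), edges, table, prior)


def select_sample_time(
    label: SepsisLabel,
    horizon_h: int,
    n_hours: int,
    rng: np.random.Generator,
) -> int:
    """Prediction hour t for one stay at a given horizon.

    Septic stays are sampled at onset minus horizon (guaranteed >= 3 by
    the >=7-hour onset inclusion rule); nonseptic stays at a seeded
    uniform random hour late enough to form the two-hour window.
    """
    if label.is_septic:
        t = label.onset_hour - horizon_h
    else:
        lo = max(2, 7 - horizon_h)
        hi = max(lo, n_hours)
        t = int(rng.integers(lo, hi + 1))
    if t < 2:
        raise ValueError(
            f"stay {label.stay_id}: insufficient history to form the two-hour window (t={t})"
        )
    return t


def raw_window(timeline: StayTimeline, t: int) -> np.ndarray:
    """The 15 raw inputs at prediction hour t: x1 (7 dynamic + age), x2 (7 dynamic).

    x1 is the bin covering (t-1, t] and x2 the bin covering (t-2, t-1],
    i.e. hourly bin indices t-1 and t-2 of the imputed timeline.
    """
    if t < 2 or t > timeline.n_hours:
        raise ValueError(f"prediction hour {t} outside [2, {timeline.n_hours}]")
    x1 = [timeline.values[ch][t - 1] for ch in DYNAMIC_PREDICTORS]
    x2 = [timeline.values[ch][t - 2] for ch in DYNAMIC_PREDICTORS]
    return np.array(x1 + [timeline.age_years] + x2, dtype=float)


def build_raw_matrix(
    timelines: dict[object, StayTimeline], times: dict[object, int], stay_ids
) -> np.ndarray:
    """Stack raw two-hour windows for a list of stays into an (n, 15) matrix."""
    return np.vstack([raw_window(timelines[sid], times[sid]) for sid in stay_ids])


class InsightFeaturizer(TransformerMixin, BaseEstimator):
    """Expand raw two-hour vitals windows into the full feature vector.

    Input X has 15 columns: the 7 dynamic predictors at x1, age, then the
    7 dynamic predictors at x2.  ``transform`` emits, in fixed order:
    z-scored x1 (8), z-scored x2 (7), 1-D level posteriors (8), 1-D delta
    posteriors (7), pairwise delta-table posteriors (C(7,2)=21 by
    default) and triple delta-table posteriors (C(7,3)=35), for a default
    width of 86.

    Parameters
    ----------
    n_bins_1d : bins for the 1-D quantile maps.
    bins_per_var : bins per variable in the delta tables.
    alpha : shrinkage strength toward the training prevalence.
    pairs, triples : "all" or an explicit list of dynamic-channel index
        tuples, to restrict which delta combinations are tabulated.
    """

    def __init__(self, n_bins_1d=20, bins_per_var=5, alpha=10.0, pairs="all", triples="all"):
        self.n_bins_1d = n_bins_1d
        self.bins_per_var = bins_per_var
        self.alpha = alpha
        self.pairs = pairs
        self.triples = triples

    def _combos(self):
        pairs = (
            list(combinations(range(N_DYNAMIC), 2)) if self.pairs == "all" else list(self.pairs)
        )
        triples = (
            list(combinations(range(N_DYNAMIC), 3))
            if self.triples == "all"
            else list(self.triples)
        )
        return pairs, triples

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, int)
        if X.ndim != 2 or X.shape[1] != RAW_WIDTH:
            raise ValueError(f"expected raw matrix with {RAW_WIDTH} columns")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        self.prior_ = float(y.mean())

        deltas = X[:, :N_DYNAMIC] - X[:, N_X1:]
        level_names = list(DYNAMIC_PREDICTORS) + ["age"]
        self.level_maps_ = [
            fit_posterior_1d(X[:, i], y, self.n_bins_1d, self.alpha, level_names[i], "level")
            for i in range(N_X1)
        ]
        self.delta_maps_ = [
            fit_posterior_1d(
                deltas[:, i], y, self.n_bins_1d, self.alpha, DYNAMIC_PREDICTORS[i], "delta"
            )
            for i in range(N_DYNAMIC)
        ]
        pairs, triples = self._combos()
        self.pair_tables_ = [
            fit_posterior_table(deltas, y, c, self.bins_per_var, self.alpha) for c in pairs
        ]
        self.triple_tables_ = [
            fit_posterior_table(deltas, y, c, self.bins_per_var, self.alpha) for c in triples
        ]
        self.feature_names_ = (
            [f"x1_{n}_z" for n in level_names]
            + [f"x2_{n}_z" for n in DYNAMIC_PREDICTORS]
            + [f"p_x1_{n}" for n in level_names]
            + [f"p_dx_{n}" for n in DYNAMIC_PREDICTORS]
            + ["p_dx_" + "_".join(DYNAMIC_PREDICTORS[i] for i in c) for c in pairs]
            + ["p_dx_" + "_".join(DYNAMIC_PREDICTORS[i] for i in c) for c in triples]
        )
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X):
        check_is_fitted(self, "level_maps_")
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != RAW_WIDTH:
            raise ValueError(f"expected raw matrix with {RAW_WIDTH} columns")
        deltas = X[:, :N_DYNAMIC] - X[:, N_X1:]
        z = (X - self.mean_) / self.scale_
        blocks = [z[:, :N_X1], z[:, N_X1:]]
        blocks.append(np.column_stack([m(X[:, i]) for i, m in enumerate(self.level_maps_)]))
        blocks.append(np.column_stack([m(deltas[:, i]) for i, m in enumerate(self.delta_maps_)]))
        for tables in (self.pair_tables_, self.triple_tables_):
            if tables:
                blocks.append(
                    np.column_stack([tab(deltas[:, list(tab.combo)]) for tab in tables])
                )
        return np.hstack(blocks)


def assemble_feature_vector(
    timeline: StayTimeline, t: int, featurizer: InsightFeaturizer
) -> np.ndarray:
    """The full feature vector for one stay at prediction hour t.

    The featurizer must already be fitted on training-fold rows.
    """
    raw = raw_window(timeline, t)
    if np.isnan(raw).any():
        missing = [
            name
            for name, bad in zip(list(DYNAMIC_PREDICTORS) + ["age"] + list(DYNAMIC_PREDICTORS),
                                 np.isnan(raw))
            if bad
        ]
        raise ValueError(f"incomplete stay {timeline.stay_id}: missing {sorted(set(missing))}")
    return featurizer.transform(raw.reshape(1, -1))[0]
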