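"""Time-resolved multivariate decoding and temporal generalization.

At every sample of the epoch a linear SVM is trained on the channel vector
to separate the two emotion categories, under stratified k-fold
cross-validation repeated with fresh random partitions; performance is the
area under the ROC curve (AUC) of the held-out decision scores, chance
0.5.  Temporal generalization trains at one time point and tests the same
held-out trials at every other time point, reusing the identical CV
partitions so training trials never leak into any test time point.

Defaults follow the analysis design: 8 folds x 8 repeats, all channels as
features, one trial = one sample (no pseudo-trial averaging), per-fold
train-set standardization, fixed C = 1.  The SVM is solved in the primal
(``dual=False``): the dual coordinate-descent solver stalls on
non-separable (chance-level) data while the primal solution is equivalent
for decoding purposes.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .containers import EpochSet, GeneralizationMatrix, TimeCourse

__all__ = [
    "compute_auc",
    "decode_timecourse",
    "temporal_generalization",
    "category_labels",
]


def category_labels(epochs: EpochSet) -> np.ndarray:
    """Boolean per-trial labels: True for positive-category trials."""
    return (epochs.trial_meta["category"].to_numpy() == "positive").astype(bool)


def compute_auc(scores, labels) -> float:
    """Rank-based AUC: P(score+ > score-) + 0.5 P(tie) over between-class
    pairs.  ``labels`` must contain both classes; the larger label value is
    the positive class."""
    scores = np.asarray(scores, dtype=float)
    y = _binary(labels)
    return float(_auc_columns(scores[:, None], y)[0])


def _binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    return y == classes[1]


def _auc_columns(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """AUC per column of ``scores`` (n_obs x n_cols) for boolean ``y``.

    Mann-Whitney identity with average ranks, which handles ties as half
    wins."""
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores, axis=0)
    return (ranks[y].sum(axis=0) - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def _cv_splits(y: np.ndarray, n_folds: int, n_repeats: int, seed: int):
    """Stratified fold assignments; each repeat uses a fresh partition."""
    counts = np.bincount(y.astype(int))
    if counts.min() < n_folds:
        raise ValueError(
            f"each class needs at least n_folds={n_folds} trials "
            f"(smallest class has {counts.min()})"
        )
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_repeats) >> np.uint32(1)
    splits = []
    for rs in rep_seeds:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(rs))
        splits.extend(skf.split(np.zeros(len(y)), y))
    return splits


def _fit_fold(X_tr: np.ndarray, y_tr: np.ndarray, clf) -> tuple[np.ndarray, np.ndarray]:
    """Per-time-point SVM fits on pre-standardized data.

    ``X_tr`` is trials x channels x times; returns weights (times x
    channels) and intercepts (times,)."""
    n_times = X_tr.shape[2]
    W = np.empty((n_times, X_tr.shape[1]))
    b = np.empty(n_times)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for t in range(n_times):
            clf.fit(X_tr[:, :, t], y_tr)
            W[t] = clf.coef_[0]
            b[t] = clf.intercept_[0]
    return W, b


def _standardize(X: np.ndarray, tr: np.ndarray):
    """Train-set mean/SD per channel and time; zero-variance guarded."""
    mean = X[tr].mean(axis=0)
    sd = X[tr].std(axis=0)
    sd[sd == 0] = 1.0
    return mean, sd


def decode_timecourse(
    epochs: EpochSet,
    labels,
    n_folds: int = 8,
    n_repeats: int = 8,
    seed: int = 0,
    C: float = 1.0,
) -> TimeCourse:
    """Mean cross-validated AUC of a linear SVM at every time point."""
    y = _binary(labels)
    X = epochs.data
    splits = _cv_splits(y, n_folds, n_repeats, seed)
    clf = LinearSVC(C=C, dual=False, tol=1e-3)
    auc = np.zeros(epochs.n_samples)
    for tr, te in splits:
        mean, sd = _standardize(X, tr)
        W, b = _fit_fold((X[tr] - mean) / sd, y[tr], clf)
        Z_te = (X[te] - mean) / sd
        scores = np.einsum("nct,tc->nt", Z_te, W) + b
        auc += _auc_columns(scores, y[te])
    auc /= len(splits)
    subject = epochs.trial_meta["subject_id"].iloc[0] if epochs.n_trials else None
    return TimeCourse(epochs.times, auc, subject_id=subject, statistic_name="auc")


def temporal_generalization(
    epochs: EpochSet,
    labels,
    n_folds: int = 8,
    n_repeats: int = 8,
    seed: int = 0,
    C: float = 1.0,
) -> GeneralizationMatrix:
    """Train at each time point, test the held-out trials at every time
    point; the diagonal is the standard time-resolved decoding."""
    y = _binary(labels)
    X = epochs.data
    n_times = epochs.n_samples
    splits = _cv_splits(y, n_folds, n_repeats, seed)
    clf = LinearSVC(C=C, dual=False, tol=1e-3)
    auc = np.zeros((n_times, n_times))
    for tr, te in splits:
        mean, sd = _standardize(X, tr)
        W, b = _fit_fold((X[tr] - mean) / sd, y[tr], clf)
        for t in range(n_times):
            # the train-time pipeline (per-channel stats at t) is applied
            # unchanged to every test time point
            Z = (X[te] - mean[None, :, t, None]) / sd[None, :, t, None]
            scores = np.einsum("ncu,c->nu", Z, W[t]) + b[t]
            auc[t] += _auc_columns(scores, y[te])
    auc /= len(splits)
    subject = epochs.trial_meta["subject_id"].iloc[0] if epochs.n_trials else None
    return GeneralizationMatrix(epochs.times, epochs.times, auc, subject_id=subject)
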