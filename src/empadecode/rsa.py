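"""Decoding-based representational similarity analysis.

The neural representational dissimilarity matrix (RDM) at each time point
holds, for every unordered stimulus pair, the cross-validated accuracy of
a shrinkage-regularized linear discriminant analysis (LDA) classifier
separating the two stimuli's channel patterns — higher decodability means
greater representational dissimilarity.  Two theoretical model RDMs are
available: a low-level attribute model (Euclidean distance in the
standardized luminance/contrast plane) and an emotion-category model
(within-category dissimilarity 0.5, between-category 1).  Model fit over
time is the Spearman rank correlation between the vectorized lower
triangles of the neural and model RDMs.

With ~30 trials per pair and 64 channels the within-class covariance is
singular, so the LDA pools the class-centered covariance and shrinks it
toward a scaled identity with the Ledoit-Wolf automatic intensity.  The
estimator is vectorized across time points (batched covariance, shrinkage
and linear solves) because a 20-stimulus design needs 190 pairwise
classifiers at every sample; the batched estimator matches
scikit-learn's ``LinearDiscriminantAnalysis(solver='lsqr')`` decision rule
at equal shrinkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .containers import EpochSet, RDMSeries, TimeCourse

__all__ = [
    "ModelRDM",
    "neural_rdm_series",
    "lowlevel_model_rdm",
    "category_model_rdm",
    "rsa_timecourse",
]


@dataclass
class ModelRDM:
    """Theoretical stimulus dissimilarity structure."""

    matrix: np.ndarray
    stimulus_ids: np.ndarray
    kind: str  # "lowlevel" | "category"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.stimulus_ids = np.asarray(self.stimulus_ids)
        n = len(self.stimulus_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("model RDM must be square on the stimulus set")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("model RDM must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("model RDM diagonal must be zero")

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(len(self.stimulus_ids), k=-1)
        return self.matrix[i, j]

    def permuted(self, perm: np.ndarray) -> "ModelRDM":
        """Apply one stimulus permutation jointly to rows and columns."""
        perm = np.asarray(perm)
        return ModelRDM(self.matrix[np.ix_(perm, perm)], self.stimulus_ids, self.kind)


# ---------------------------------------------------------------------------
# batched shrinkage LDA
# ---------------------------------------------------------------------------

def _lw_shrinkage_batched(Xc: np.ndarray, S_sum: np.ndarray) -> np.ndarray:
    """Ledoit-Wolf shrinkage intensity per time point.

    ``Xc`` is class-centered data (n x channels x times), ``S_sum`` the
    per-time scatter matrices ``X.T X`` (times x C x C).  Follows the
    standard estimator: shrink toward mu*I with intensity
    min(beta, delta)/delta.
    """
    n, p, _ = Xc.shape[0], Xc.shape[1], Xc.shape[2]
    X2 = Xc**2
    trace_sum = X2.sum(axis=(0, 1))  # per time: sum of emp_cov_trace * n
    mu = trace_sum / (n * p)
    beta_sum = (X2.sum(axis=1) ** 2).sum(axis=0)  # sum_n (sum_c X2)^2 per time
    delta_sum = (S_sum**2).sum(axis=(1, 2))
    delta_ = delta_sum / n**2
    beta = (beta_sum / n - delta_) / (p * n)
    delta = (delta_ - 2.0 * mu * (trace_sum / n) + p * mu**2) / p
    with np.errstate(invalid="ignore", divide="ignore"):
        shrinkage = np.where(beta > 0, np.minimum(beta, delta) / delta, 0.0)
    return np.clip(np.nan_to_num(shrinkage), 0.0, 1.0)


def _lda_fold_accuracy(
    X_tr_a: np.ndarray,
    X_tr_b: np.ndarray,
    X_te_a: np.ndarray,
    X_te_b: np.ndarray,
    shrinkage: float | None = None,
) -> np.ndarray:
    """Correct-classification counts per time point for one CV fold.

    Arrays are trials x channels x times.  Returns the number of correct
    test predictions at each time (caller divides by the test count).
    """
    m_a = X_tr_a.mean(axis=0)  # C x T
    m_b = X_tr_b.mean(axis=0)
    Xc = np.concatenate([X_tr_a - m_a, X_tr_b - m_b], axis=0)
    n = Xc.shape[0]
    S_sum = np.einsum("nct,ndt->tcd", Xc, Xc)
    S = S_sum / n  # pooled, class-centered, biased denominator
    if shrinkage is None:
        alpha = _lw_shrinkage_batched(Xc, S_sum)
    else:
        alpha = np.full(S.shape[0], float(shrinkage))
    p = S.shape[1]
    mu = np.trace(S, axis1=1, axis2=2) / p
    Sigma = (1.0 - alpha)[:, None, None] * S
    idx = np.arange(p)
    Sigma[:, idx, idx] += (alpha * mu)[:, None]
    diff = (m_b - m_a).T[:, :, None]  # T x C x 1
    w = np.linalg.solve(Sigma, diff)[:, :, 0]  # T x C
    mid = ((m_a + m_b) / 2.0).T  # T x C
    thresh = np.einsum("tc,tc->t", mid, w)
    score_a = np.einsum("nct,tc->nt", X_te_a, w) - thresh
    score_b = np.einsum("nct,tc->nt", X_te_b, w) - thresh
    return (score_a < 0).sum(axis=0) + (score_b > 0).sum(axis=0)


def _stratified_pair_folds(n_a: int, n_b: int, cv_folds: int, rng: np.random.Generator):
    """Fold labels for the two classes of one pair."""
    fa = rng.permutation(np.arange(n_a) % cv_folds)
    fb = rng.permutation(np.arange(n_b) % cv_folds)
    return fa, fb


def neural_rdm_series(
    epochs: EpochSet,
    stimulus_ids=None,
    cv_folds: int = 4,
    seed: int = 0,
    shrinkage: float | None = None,
) -> RDMSeries:
    """Time series of pairwise-decoding RDMs for one subject.

    For every unordered stimulus pair and every time point, the
    cross-validated shrinkage-LDA accuracy on that pair's trials (channel
    vectors as features), written symmetrically into an n_stim x n_stim
    matrix.  ``shrinkage=None`` selects the Ledoit-Wolf automatic
    intensity per fold and time point.
    """
    if stimulus_ids is None:
        stimulus_ids = epochs.trial_meta["stimulus_id"].to_numpy()
    stimulus_ids = np.asarray(stimulus_ids)
    if len(stimulus_ids) != epochs.n_trials:
        raise ValueError("stimulus_ids must be per trial")
    unique_ids = np.unique(stimulus_ids)
    n_stim = len(unique_ids)
    if n_stim < 2:
        raise ValueError("need at least 2 stimuli")
    trial_idx = {s: np.flatnonzero(stimulus_ids == s) for s in unique_ids}
    for s, idx in trial_idx.items():
        if len(idx) < cv_folds:
            raise ValueError(f"stimulus {s} has fewer trials ({len(idx)}) than cv_folds")

    rng = np.random.default_rng(seed)
    n_times = epochs.n_samples
    matrices = np.zeros((n_times, n_stim, n_stim))
    X = epochs.data
    for ia in range(n_stim):
        for ib in range(ia + 1, n_stim):
            idx_a = trial_idx[unique_ids[ia]]
            idx_b = trial_idx[unique_ids[ib]]
            fa, fb = _stratified_pair_folds(len(idx_a), len(idx_b), cv_folds, rng)
            correct = np.zeros(n_times)
            n_test = 0
            for f in range(cv_folds):
                te_a, te_b = idx_a[fa == f], idx_b[fb == f]
                tr_a, tr_b = idx_a[fa != f], idx_b[fb != f]
                correct += _lda_fold_accuracy(
                    X[tr_a], X[tr_b], X[te_a], X[te_b], shrinkage=shrinkage
                )
                n_test += len(te_a) + len(te_b)
            acc = correct / n_test
            matrices[:, ia, ib] = acc
            matrices[:, ib, ia] = acc
    subject = epochs.trial_meta["subject_id"].iloc[0] if epochs.n_trials else None
    return RDMSeries(epochs.times, matrices, unique_ids, subject_id=subject)


# ---------------------------------------------------------------------------
# model RDMs
# ---------------------------------------------------------------------------

def lowlevel_model_rdm(stimuli: pd.DataFrame, standardize: bool = True) -> ModelRDM:
    """Euclidean distance between stimuli in the (luminance, contrast)
    plane; features are z-scored across stimuli by default so neither
    dominates by scale alone."""
    for col in ("luminance", "contrast"):
        if col not in stimuli or stimuli[col].isna().any():
            raise ValueError(f"stimulus feature '{col}' missing")
    feats = stimuli[["luminance", "contrast"]].to_numpy(dtype=float)
    if standardize:
        feats = (feats - feats.mean(0)) / feats.std(0)
    mat = squareform(pdist(feats, metric="euclidean"))
    return ModelRDM(mat, stimuli["stimulus_id"].to_numpy(), kind="lowlevel")


def category_model_rdm(stimuli: pd.DataFrame) -> ModelRDM:
    """Binary-valence model: within-category pairs 0.5, between 1.0."""
    if "category" not in stimuli or stimuli["category"].isna().any():
        raise ValueError("stimulus category missing")
    cats = stimuli["category"].to_numpy()
    same = cats[:, None] == cats[None, :]
    mat = np.where(same, 0.5, 1.0)
    np.fill_diagonal(mat, 0.0)
    return ModelRDM(mat, stimuli["stimulus_id"].to_numpy(), kind="category")


# ---------------------------------------------------------------------------
# model correlation over time
# ---------------------------------------------------------------------------

def _rank_normalize(X: np.ndarray, axis: int = -1) -> np.ndarray:
    """Average ranks, centered and scaled to unit norm along ``axis`` (so a
    dot product of two such vectors is the Spearman correlation).
    Constant vectors come back as all-NaN."""
    R = rankdata(X, axis=axis)
    R = R - R.mean(axis=axis, keepdims=True)
    norm = np.linalg.norm(R, axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(norm > 0, R / norm, np.nan)


def spearman_to_model(lower_tris: np.ndarray, model_vec: np.ndarray) -> np.ndarray:
    """Spearman rho between each row of ``lower_tris`` (n_times x n_pairs)
    and ``model_vec``; ties get average ranks, constant inputs give NaN."""
    Rn = _rank_normalize(np.asarray(lower_tris, dtype=float))
    rm = _rank_normalize(np.asarray(model_vec, dtype=float)[None, :])[0]
    return Rn @ rm


def rsa_timecourse(neural: RDMSeries, model: ModelRDM) -> TimeCourse:
    """Per-time-point Spearman correlation between the neural RDM and the
    model RDM (vectorized lower triangles).  Time points with a constant
    dissimilarity vector yield NaN (treated as sub-threshold downstream)."""
    if len(model.stimulus_ids) != neural.n_stim or not np.array_equal(
        np.sort(model.stimulus_ids), np.sort(neural.stimulus_ids)
    ):
        raise ValueError("neural and model RDMs must cover the same stimuli")
    if not np.array_equal(model.stimulus_ids, neural.stimulus_ids):
        order = np.argsort(model.stimulus_ids)[np.argsort(np.argsort(neural.stimulus_ids))]
        model = model.permuted(order)
    rho = spearman_to_model(neural.lower_triangles(), model.lower_triangle())
    if np.isnan(rho).any():
        warnings.warn("undefined Spearman rho at some time points (constant vector)")
    return TimeCourse(
        neural.times,
        rho,
        subject_id=neural.subject_id,
        statistic_name=f"rho_{model.kind}",
        chance_level=0.0,
    )
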