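"""Non-parametric cluster-based permutation inference.

Point-level statistics are one-tailed Wilcoxon signed-rank tests across
subjects (exact enumeration of sign patterns for small n, tie-corrected
normal approximation otherwise).  Contiguous supra-threshold points
(p < alpha, one-tailed) form clusters whose mass is the summed
standardized point statistic ("maxsum").  Cluster-level significance
comes from a permutation null of maximum cluster masses with the add-one
estimator p = (1 + #{null >= observed}) / (1 + n_perm):

* against chance (decoding AUC / any statistic vs a fixed chance level):
  per permutation the sign of each subject's whole deviation time course
  is flipped independently, preserving temporal autocorrelation;
* against zero model correlation (RSA): per permutation one shared random
  stimulus permutation is applied jointly to the model RDM's rows and
  columns and every subject's correlation time course is recomputed;
* within a single subject: trial labels are shuffled and the decoding
  rerun, with pointwise p-values taken from the pooled permutation
  distribution.

Only one-tailed positive clusters are formed (the analyses test "above
chance" and "positive correlation").
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from scipy.stats import norm, rankdata

from .containers import Cluster, ClusterTestResult, EpochSet, RDMSeries, TimeCourse
from .mvpa import decode_timecourse
from .rsa import ModelRDM, _rank_normalize, spearman_to_model

__all__ = [
    "wilcoxon_pointwise",
    "form_clusters",
    "permtest_vs_chance",
    "permtest_rsa",
    "permtest_single_subject",
    "SignedRank",
]


class SignedRank:
    """Vectorized one-tailed Wilcoxon signed-rank machinery.

    Operates column-wise on a differences matrix ``D`` (n_subjects x
    n_points).  Exact zeros and non-finite entries are excluded per column
    (the standard zero-discard convention); ranks of |D| use average ranks
    for ties.  For columns with n_eff <= ``exact_max`` the one-tailed p is
    computed by enumerating all 2^n sign patterns, otherwise by the normal
    approximation with tie correction.
    """

    def __init__(self, D: np.ndarray, exact_max: int = 12):
        D = np.asarray(D, dtype=float)
        if D.ndim != 2:
            raise ValueError("D must be 2D (subjects x points)")
        self.D = D
        n, T = D.shape
        self.valid = np.isfinite(D) & (D != 0.0)
        self.n_eff = self.valid.sum(axis=0)
        # ranks of |D| among valid entries, 0 at excluded entries
        self.R = np.zeros_like(D)
        clean = self.valid.all(axis=0)
        if clean.any():
            self.R[:, clean] = rankdata(np.abs(D[:, clean]), axis=0)
        for t in np.flatnonzero(~clean):
            v = self.valid[:, t]
            if v.any():
                self.R[v, t] = rankdata(np.abs(D[v, t]))
        ne = self.n_eff.astype(float)
        self.E = ne * (ne + 1) / 4.0
        var = ne * (ne + 1) * (2 * ne + 1) / 24.0 - self._tie_correction() / 48.0
        self.sd = np.sqrt(np.maximum(var, 0.0))
        self.exact_max = exact_max
        self._shared_null = None
        self._col_nulls: dict[int, np.ndarray] = {}
        self._prepare_exact()

    def _tie_correction(self) -> np.ndarray:
        out = np.zeros(self.R.shape[1])
        for t in range(self.R.shape[1]):
            r = self.R[self.valid[:, t], t]
            if len(r) == 0:
                continue
            _, counts = np.unique(r, return_counts=True)
            out[t] = np.sum(counts.astype(float) ** 3 - counts)
        return out

    def _prepare_exact(self) -> None:
        self._exact_cols = np.flatnonzero((self.n_eff > 0) & (self.n_eff <= self.exact_max))
        if len(self._exact_cols) == 0:
            return
        n = self.D.shape[0]
        # shared null when every column has the untied full rank set 1..n
        if np.all(self.n_eff == n):
            no_ties = all(
                len(np.unique(self.R[:, t])) == n for t in self._exact_cols
            )
            if no_ties:
                self._shared_null = np.sort(_subset_sums(np.arange(1.0, n + 1)))
                return
        for t in self._exact_cols:
            r = self.R[self.valid[:, t], t]
            self._col_nulls[t] = np.sort(_subset_sums(r))

    # -- statistics -------------------------------------------------------
    def W(self, signs: np.ndarray | None = None) -> np.ndarray:
        """Signed-rank sums W+.

        Without ``signs``: the observed per-column W+ (1D).  With a
        (n_perm x n_subjects) matrix of +/-1 sign flips: W+ per permutation
        and column (2D)."""
        pos = self.R * (self.D > 0)
        if signs is None:
            return pos.sum(axis=0)
        neg = self.R * (self.D < 0)
        S = np.asarray(signs)
        return (S > 0) @ pos + (S < 0) @ neg

    def z_of(self, W: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (W - self.E) / self.sd
        return np.where(self.sd > 0, z, np.nan)

    def p_of(self, W: np.ndarray) -> np.ndarray:
        """One-tailed (greater) p per column; exact where prepared."""
        W = np.asarray(W, dtype=float)
        p = norm.sf(np.nan_to_num(self.z_of(W), nan=0.0))
        p = np.where(self.sd > 0, p, np.nan)
        for t in self._exact_cols:
            null = self._shared_null if self._shared_null is not None else self._col_nulls[t]
            m = len(null)
            w_t = W[..., t]
            count_ge = m - np.searchsorted(null, w_t, side="left")
            p[..., t] = count_ge / m
        return p


def _subset_sums(ranks: np.ndarray) -> np.ndarray:
    """All 2^n signed-rank sums W+ under the exchangeable-signs null."""
    sums = np.zeros(1)
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    return sums


def wilcoxon_pointwise(samples, null_value: float = 0.0, tail: str = "greater"):
    """One-sample, one-tailed Wilcoxon signed-rank test of ``samples``
    against ``null_value``.  Returns (W+, p).  Exact p for n <= 12 after
    dropping zero differences, normal approximation with tie correction
    above.  All-zero differences are undefined (returns (nan, nan) with a
    warning)."""
    if tail != "greater":
        raise ValueError("only the one-tailed 'greater' test is implemented")
    d = np.asarray(samples, dtype=float) - null_value
    n_eff = int(np.sum(np.isfinite(d) & (d != 0)))
    if n_eff == 0:
        warnings.warn("all differences equal the null value; test undefined")
        return np.nan, np.nan
    if n_eff < 5:
        raise ValueError("need at least 5 non-zero differences")
    m = SignedRank(d[:, None])
    W = m.W()
    return float(W[0]), float(m.p_of(W)[0])


# ---------------------------------------------------------------------------
# cluster formation
# ---------------------------------------------------------------------------

def form_clusters(
    point_p: np.ndarray,
    point_stats: np.ndarray,
    alpha_point: float = 0.05,
    adjacency: str | None = None,
) -> list[Cluster]:
    """Maximal connected supra-threshold (p < alpha) components.

    1D maps use run contiguity; 2D maps 4-connectivity.  NaN p-values are
    sub-threshold.  Cluster mass is the sum of ``point_stats`` over
    members."""
    point_p = np.asarray(point_p, dtype=float)
    point_stats = np.asarray(point_stats, dtype=float)
    if point_p.shape != point_stats.shape:
        raise ValueError("point_p and point_stats shapes must match")
    if adjacency is None:
        adjacency = "2d" if point_p.ndim == 2 else "1d"
    supra = np.nan_to_num(point_p, nan=1.0) < alpha_point
    clusters: list[Cluster] = []
    if adjacency == "1d":
        labeled, n = ndimage.label(supra)
        for k in range(1, n + 1):
            idx = np.flatnonzero(labeled == k)
            clusters.append(Cluster(indices=idx, mass=float(point_stats[idx].sum())))
    elif adjacency == "2d":
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        labeled, n = ndimage.label(supra, structure=structure)
        for k in range(1, n + 1):
            rows, cols = np.nonzero(labeled == k)
            mass = float(point_stats[rows, cols].sum())
            clusters.append(Cluster(indices=np.column_stack([rows, cols]), mass=mass))
    else:
        raise ValueError("adjacency must be '1d' or '2d'")
    return clusters


def _max_mass_1d(p_row: np.ndarray, stat_row: np.ndarray, alpha: float) -> float:
    """Largest cluster mass of one (possibly flattened-from-2D) stat map."""
    cl = form_clusters(p_row, stat_row, alpha_point=alpha)
    return max((c.mass for c in cl), default=0.0)


def _cluster_p(observed: list[Cluster], null_max: np.ndarray, n_perm: int) -> None:
    for c in observed:
        c.p_value = float((1 + np.sum(null_max >= c.mass)) / (1 + n_perm))


# ---------------------------------------------------------------------------
# group-level test against chance (sign-flip null)
# ---------------------------------------------------------------------------

def _stack_courses(objects) -> tuple[np.ndarray, np.ndarray, tuple[int, ...]]:
    """Common time axis + stacked values from TimeCourses or
    GeneralizationMatrices; values flattened to (n_subj, n_points)."""
    first = objects[0]
    if isinstance(first, TimeCourse):
        times = first.times
        shape: tuple[int, ...] = times.shape
        mats = []
        for tc in objects:
            if not np.array_equal(tc.times, times):
                raise ValueError("subjects must share one time axis")
            mats.append(tc.values)
    else:  # GeneralizationMatrix
        times = first.train_times
        shape = first.values.shape
        mats = []
        for gm in objects:
            if not np.array_equal(gm.train_times, times):
                raise ValueError("subjects must share one time axis")
            mats.append(gm.values.ravel())
    return times, np.asarray(mats).reshape(len(objects), -1), shape


def permtest_vs_chance(
    subject_timecourses,
    chance: float = 0.5,
    n_perm: int = 1000,
    seed: int = 0,
    alpha_point: float = 0.05,
    alpha_cluster: float = 0.05,
) -> ClusterTestResult:
    """Group-level cluster permutation test of a statistic against a fixed
    chance level.

    Accepts per-subject :class:`TimeCourse` (1D clusters) or
    :class:`GeneralizationMatrix` (2D, 4-connectivity) objects.  The null
    flips the sign of each subject's whole deviation map independently,
    so the temporal (and train/test) correlation structure is preserved
    under the null.
    """
    if len(subject_timecourses) < 5:
        raise ValueError("need at least 5 subjects")
    times, D, shape = _stack_courses(subject_timecourses)
    D = D - chance
    n_subj = D.shape[0]
    machinery = SignedRank(D)
    W_obs = machinery.W()
    p_obs = machinery.p_of(W_obs)
    z_obs = machinery.z_of(W_obs)
    adjacency = "2d" if len(shape) == 2 else "1d"
    clusters = form_clusters(
        p_obs.reshape(shape), z_obs.reshape(shape), alpha_point, adjacency
    )

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    W_perm = machinery.W(signs)
    p_perm = machinery.p_of(W_perm)
    z_perm = machinery.z_of(W_perm)
    null_max = np.array(
        [
            _max_mass_1d(
                p_perm[b].reshape(shape), np.nan_to_num(z_perm[b].reshape(shape)), alpha_point
            )
            for b in range(n_perm)
        ]
    )
    _cluster_p(clusters, null_max, n_perm)
    return ClusterTestResult(
        point_stats=z_obs.reshape(shape),
        point_p=p_obs.reshape(shape),
        clusters=clusters,
        null_distribution=null_max,
        alpha_cluster=alpha_cluster,
        n_permutations=n_perm,
        times=times,
    )


# ---------------------------------------------------------------------------
# group-level RSA test (model-RDM shuffle null)
# ---------------------------------------------------------------------------

def permtest_rsa(
    neural_rdms: list[RDMSeries],
    model: ModelRDM,
    n_perm: int = 1000,
    seed: int = 0,
    alpha_point: float = 0.05,
    alpha_cluster: float = 0.05,
) -> ClusterTestResult:
    """Cluster permutation test of the subject Spearman rho time courses
    against zero.

    The null reshuffles the model RDM's rows and columns with one shared
    random stimulus permutation per iteration (identity excluded) and
    recomputes every subject's rho course, leaving the neural data — and
    hence its dependence structure — untouched.
    """
    if len(neural_rdms) < 5:
        raise ValueError("need at least 5 subjects")
    times = neural_rdms[0].times
    n_stim = neural_rdms[0].n_stim
    for r in neural_rdms:
        if not np.array_equal(r.times, times) or r.n_stim != n_stim:
            raise ValueError("subjects must share time axis and stimulus set")
    model_vec = model.lower_triangle()
    # pre-rank the neural lower triangles once; rho = ranks . model-ranks
    Rn = np.stack([_rank_normalize(r.lower_triangles()) for r in neural_rdms])
    rm = _rank_normalize(model_vec[None, :])[0]
    rho_obs = np.einsum("stp,p->st", np.nan_to_num(Rn), rm)
    rho_obs[np.isnan(Rn).any(axis=2)] = np.nan

    machinery = SignedRank(rho_obs)
    W = machinery.W()
    p_obs, z_obs = machinery.p_of(W), machinery.z_of(W)
    clusters = form_clusters(p_obs, z_obs, alpha_point, "1d")

    rng = np.random.default_rng(seed)
    i_low, j_low = np.tril_indices(n_stim, k=-1)
    null_max = np.empty(n_perm)
    mat = model.matrix
    for b in range(n_perm):
        while True:
            perm = rng.permutation(n_stim)
            if not np.array_equal(perm, np.arange(n_stim)):
                break
        vec = mat[np.ix_(perm, perm)][i_low, j_low]
        rmp = _rank_normalize(vec[None, :])[0]
        rho = np.einsum("stp,p->st", np.nan_to_num(Rn), rmp)
        rho[np.isnan(Rn).any(axis=2)] = np.nan
        mp = SignedRank(rho)
        Wp = mp.W()
        null_max[b] = _max_mass_1d(mp.p_of(Wp), np.nan_to_num(mp.z_of(Wp)), alpha_point)
    _cluster_p(clusters, null_max, n_perm)
    return ClusterTestResult(
        point_stats=z_obs,
        point_p=p_obs,
        clusters=clusters,
        null_distribution=null_max,
        alpha_cluster=alpha_cluster,
        n_permutations=n_perm,
        times=times,
    )


# ---------------------------------------------------------------------------
# single-subject test (trial-label shuffle null)
# ---------------------------------------------------------------------------

def permtest_single_subject(
    epochs: EpochSet,
    labels,
    n_perm: int = 100,
    seed: int = 0,
    n_folds: int = 8,
    n_repeats: int = 8,
    alpha_point: float = 0.05,
    alpha_cluster: float = 0.05,
    chance: float = 0.5,
) -> tuple[TimeCourse, ClusterTestResult]:
    """Within-subject cluster test of the decoding AUC time course.

    The null shuffles the trial labels and reruns the decoding; pointwise
    p-values are pooled permutation ranks (add-one), cluster mass is the
    summed AUC deviation from chance, and the null distribution collects
    each permutation's maximum cluster mass scored against the pooled
    pointwise thresholds."""
    y = np.asarray(labels)
    observed = decode_timecourse(epochs, y, n_folds=n_folds, n_repeats=n_repeats, seed=seed)
    rng = np.random.default_rng(seed)
    curves = np.empty((n_perm + 1, len(observed.values)))
    curves[0] = observed.values
    for b in range(n_perm):
        y_perm = rng.permutation(y)
        curves[b + 1] = decode_timecourse(
            epochs, y_perm, n_folds=n_folds, n_repeats=n_repeats, seed=seed
        ).values
    # pooled pointwise p: fraction of curves (incl. self) at or above
    p_all = rankdata(-curves, axis=0, method="max") / (n_perm + 1)
    stats_all = curves - chance
    clusters = form_clusters(p_all[0], stats_all[0], alpha_point, "1d")
    null_max = np.array(
        [_max_mass_1d(p_all[b + 1], stats_all[b + 1], alpha_point) for b in range(n_perm)]
    )
    _cluster_p(clusters, null_max, n_perm)
    result = ClusterTestResult(
        point_stats=stats_all[0],
        point_p=p_all[0],
        clusters=clusters,
        null_distribution=null_max,
        alpha_cluster=alpha_cluster,
        n_permutations=n_perm,
        times=observed.times,
    )
    return observed, result
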