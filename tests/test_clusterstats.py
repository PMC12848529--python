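"""Cluster permutation machinery: point tests, cluster formation, nulls."""

import itertools

import numpy as np
import pytest

from empadecode.clusterstats import (
    SignedRank,
    form_clusters,
    permtest_rsa,
    permtest_single_subject,
    permtest_vs_chance,
    wilcoxon_pointwise,
)
from empadecode.containers import TimeCourse
from empadecode.mvpa import category_labels
from empadecode.rsa import category_model_rdm, lowlevel_model_rdm, neural_rdm_series


def wilcoxon_enumeration_oracle(diffs):
    """Brute force: one-tailed P(W+ >= observed) over all 2^n sign patterns,
    with average ranks of |d|."""
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    n = len(diffs)
    absd = np.abs(diffs)
    order = np.argsort(absd)
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    w_obs = ranks[diffs > 0].sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w >= w_obs - 1e-12:
            count += 1
    return count / 2**n


def flood_fill_oracle(mask):
    """Brute-force connected components (1D runs / 2D 4-connectivity)."""
    mask = np.asarray(mask, dtype=bool)
    visited = np.zeros_like(mask)
    comps = []
    if mask.ndim == 1:
        neighbors = lambda i: [(i[0] - 1,), (i[0] + 1,)]
        indices = [(i,) for i in range(mask.shape[0])]
    else:
        neighbors = lambda i: [
            (i[0] - 1, i[1]),
            (i[0] + 1, i[1]),
            (i[0], i[1] - 1),
            (i[0], i[1] + 1),
        ]
        indices = list(itertools.product(range(mask.shape[0]), range(mask.shape[1])))
    for start in indices:
        if not mask[start] or visited[start]:
            continue
        stack, comp = [start], []
        visited[start] = True
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for nb in neighbors(cur):
                if all(0 <= c < s for c, s in zip(nb, mask.shape)):
                    if mask[nb] and not visited[nb]:
                        visited[nb] = True
                        stack.append(nb)
        comps.append(sorted(comp))
    return sorted(comps)


class TestWilcoxon:
    def test_six_positive_differences_exact_p(self):
        w, p = wilcoxon_pointwise(np.arange(1.0, 7.0), 0.0)
        assert w == 21.0
        assert p == pytest.approx(1.0 / 64.0)

    def test_symmetric_differences_give_half(self):
        _, p = wilcoxon_pointwise(np.array([3.0, -3.0, 2.0, -2.0, 1.0, -1.0]), 0.0)
        assert 0.4 <= p <= 0.7

    def test_exact_p_matches_enumeration_oracle(self, rng):
        for n in (6, 8, 10):
            for _ in range(5):
                d = np.round(rng.standard_normal(n), 2)
                d[d == 0] = 0.5
                _, p = wilcoxon_pointwise(d, 0.0)
                assert p == pytest.approx(wilcoxon_enumeration_oracle(d))

    def test_all_zero_differences_flagged(self):
        with pytest.warns(UserWarning):
            w, p = wilcoxon_pointwise(np.zeros(8), 0.0)
        assert np.isnan(w) and np.isnan(p)

    def test_too_few_nonzero_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_pointwise(np.array([1.0, 2.0, 0.0, 0.0, 0.0, 0.0]), 0.0)

    def test_normal_approximation_close_to_exact_at_boundary(self, rng):
        d = rng.standard_normal(12) + 0.5
        m_exact = SignedRank(d[:, None], exact_max=12)
        m_norm = SignedRank(d[:, None], exact_max=0)
        p_e = m_exact.p_of(m_exact.W())[0]
        p_n = m_norm.p_of(m_norm.W())[0]
        assert p_n == pytest.approx(p_e, abs=0.03)


class TestFormClusters:
    def test_hand_traced_example(self):
        clusters = form_clusters(
            np.array([0.2, 0.01, 0.02, 0.3, 0.04]), np.array([1.0, 5.0, 4.0, 1.0, 3.0])
        )
        assert len(clusters) == 2
        assert clusters[0].indices.tolist() == [1, 2] and clusters[0].mass == 9.0
        assert clusters[1].indices.tolist() == [4] and clusters[1].mass == 3.0

    def test_empty_when_nothing_supra_threshold(self):
        assert form_clusters(np.full(10, 0.5), np.ones(10)) == []

    def test_2d_cross_is_one_cluster(self):
        p = np.ones((5, 5))
        stats = np.zeros((5, 5))
        cross = [(2, 1), (2, 2), (2, 3), (1, 2), (3, 2)]
        for r, c in cross:
            p[r, c] = 0.01
            stats[r, c] = 1.0
        clusters = form_clusters(p, stats)
        assert len(clusters) == 1
        assert clusters[0].mass == 5.0

    @pytest.mark.parametrize("ndim", [1, 2])
    def test_matches_flood_fill_oracle_on_random_masks(self, ndim, rng):
        for _ in range(25):
            shape = (30,) if ndim == 1 else (8, 9)
            p = rng.uniform(0, 1, shape)
            stats = rng.standard_normal(shape)
            clusters = form_clusters(p, stats, alpha_point=0.3)
            if ndim == 1:
                got = sorted(sorted((int(i),) for i in c.indices) for c in clusters)
            else:
                got = sorted(sorted(tuple(map(int, row)) for row in c.indices) for c in clusters)
            expected = flood_fill_oracle(p < 0.3)
            assert got == expected
            for c in clusters:
                idx = tuple(np.asarray(c.indices).T) if ndim == 2 else c.indices
                assert c.mass == pytest.approx(stats[idx].sum())

    def test_nan_p_is_subthreshold(self):
        clusters = form_clusters(np.array([0.01, np.nan, 0.01]), np.ones(3))
        assert len(clusters) == 2


def _make_courses(rng, n_subj=12, effect=0.0, sd=0.02, times=None):
    if times is None:
        times = np.arange(-200.0, 501.0, 5.0)
    courses = []
    for _ in range(n_subj):
        vals = 0.5 + rng.normal(0, sd, len(times))
        vals[(times >= 100) & (times <= 400)] += effect
        courses.append(TimeCourse(times, vals))
    return courses


class TestPermtestVsChance:
    def test_recovers_injected_window(self, rng):
        res = permtest_vs_chance(_make_courses(rng, effect=0.15), n_perm=300, seed=0)
        sig = res.significant_clusters()
        assert len(sig) >= 1
        start = res.times[int(sig[0].indices.min())]
        end = res.times[int(sig[0].indices.max())]
        assert abs(start - 100) <= 25 and abs(end - 400) <= 25

    def test_add_one_p_floor_when_observed_exceeds_all_nulls(self, rng):
        res = permtest_vs_chance(_make_courses(rng, effect=0.3), n_perm=100, seed=0)
        best = min(c.p_value for c in res.clusters)
        assert best == pytest.approx(1.0 / 101.0)
        assert all(c.p_value >= 1.0 / 101.0 for c in res.clusters)

    def test_positive_offset_never_decreases_cluster_mass(self, rng):
        courses = _make_courses(rng, effect=0.05)
        res = permtest_vs_chance(courses, n_perm=50, seed=1)
        shifted = [TimeCourse(c.times, c.values + 0.01) for c in courses]
        res2 = permtest_vs_chance(shifted, n_perm=50, seed=1)
        assert sum(c.mass for c in res2.clusters) >= sum(c.mass for c in res.clusters) - 1e-9

    def test_requires_common_axis_and_enough_subjects(self, rng):
        courses = _make_courses(rng, n_subj=4)
        with pytest.raises(ValueError):
            permtest_vs_chance(courses, n_perm=10)
        courses = _make_courses(rng, n_subj=6)
        courses[2] = TimeCourse(courses[2].times + 5.0, courses[2].values)
        with pytest.raises(ValueError):
            permtest_vs_chance(courses, n_perm=10)

    def test_2d_generalization_input(self, rng):
        from empadecode.containers import GeneralizationMatrix

        times = np.arange(0.0, 100.0, 10.0)
        mats = []
        for _ in range(8):
            vals = 0.5 + rng.normal(0, 0.02, (10, 10))
            vals[3:7, 3:7] += 0.2
            mats.append(GeneralizationMatrix(times, times, vals))
        res = permtest_vs_chance(mats, n_perm=100, seed=0)
        sig = res.significant_clusters()
        assert len(sig) == 1
        rows = sig[0].indices[:, 0]
        assert rows.min() >= 3 and rows.max() <= 6


class TestPermtestRsa:
    def test_category_signal_found_and_feature_signal_rejected(self, epochs_factory):
        rdms = []
        for seed in range(5):
            ep, stim = epochs_factory(
                category_amplitude=5.0,
                repetitions=4,
                seed=seed,
                n_channels=12,
                n_per_category=5,
                fs=100.0,
                window=(-100.0, 400.0),
            )
            rdms.append(neural_rdm_series(ep, cv_folds=2, seed=seed))
        cat = category_model_rdm(stim)
        res = permtest_rsa(rdms, cat, n_perm=100, seed=0)
        assert len(res.significant_clusters()) >= 1
        low = lowlevel_model_rdm(stim)
        res_low = permtest_rsa(rdms, low, n_perm=100, seed=0)
        # low-level model may catch weak structure, but the category model
        # must dominate
        mass_cat = max((c.mass for c in res.significant_clusters()), default=0)
        mass_low = max((c.mass for c in res_low.significant_clusters()), default=0)
        assert mass_cat > mass_low

    def test_p_floor_respected(self, epochs_factory):
        rdms = []
        for seed in range(5):
            ep, stim = epochs_factory(
                category_amplitude=5.0,
                repetitions=4,
                seed=seed,
                n_channels=12,
                n_per_category=5,
                fs=100.0,
                window=(-100.0, 400.0),
            )
            rdms.append(neural_rdm_series(ep, cv_folds=2, seed=seed))
        res = permtest_rsa(rdms, category_model_rdm(stim), n_perm=60, seed=3)
        assert all(c.p_value >= 1.0 / 61.0 for c in res.clusters)


class TestPermtestSingleSubject:
    def test_strong_signal_yields_covering_cluster(self, epochs_factory):
        ep, _ = epochs_factory(
            category_amplitude=5.0,
            repetitions=6,
            seed=41,
            n_channels=10,
            fs=100.0,
            window=(-100.0, 400.0),
        )
        tc, res = permtest_single_subject(
            ep, category_labels(ep), n_perm=24, seed=0, n_folds=4, n_repeats=1
        )
        sig = res.significant_clusters()
        assert len(sig) >= 1
        covered = res.times[np.concatenate([c.indices for c in sig])]
        assert covered.min() <= 130 and covered.max() >= 370

    def test_null_data_rarely_significant(self, epochs_factory):
        hits = 0
        for seed in range(3):
            ep, _ = epochs_factory(
                repetitions=4, seed=50 + seed, n_channels=8, fs=100.0, window=(-100.0, 300.0)
            )
            _, res = permtest_single_subject(
                ep, category_labels(ep), n_perm=24, seed=seed, n_folds=4, n_repeats=1
            )
            hits += len(res.significant_clusters()) > 0
        assert hits <= 1
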