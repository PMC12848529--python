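"""RSA: pairwise-decoding RDMs, model RDMs, Spearman time courses."""

import numpy as np
import pandas as pd
import pytest

from empadecode.containers import RDMSeries
from empadecode.rsa import (
    ModelRDM,
    _lda_fold_accuracy,
    _lw_shrinkage_batched,
    category_model_rdm,
    lowlevel_model_rdm,
    neural_rdm_series,
    rsa_timecourse,
    spearman_to_model,
)


def spearman_oracle(x, y):
    """Independent average-rank Spearman implementation (naive)."""

    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))


def _stim_table(n_per_cat=10, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_cat
    return pd.DataFrame(
        {
            "stimulus_id": np.arange(1, n + 1),
            "category": ["positive"] * n_per_cat + ["negative"] * n_per_cat,
            "luminance": rng.uniform(0, 1, n),
            "contrast": rng.uniform(0, 1, n),
        }
    )


class TestModelRDMs:
    def test_lowlevel_345_triangle_unstandardized(self):
        stim = pd.DataFrame(
            {
                "stimulus_id": [1, 2],
                "category": ["positive", "negative"],
                "luminance": [0.0, 3.0],
                "contrast": [0.0, 4.0],
            }
        )
        rdm = lowlevel_model_rdm(stim, standardize=False)
        assert rdm.matrix[0, 1] == pytest.approx(5.0)
        assert rdm.matrix[0, 0] == 0.0

    def test_identical_features_zero_distance(self):
        stim = _stim_table(2)
        stim.loc[:, ["luminance", "contrast"]] = 0.5
        with np.errstate(invalid="ignore", divide="ignore"):
            rdm = lowlevel_model_rdm(stim, standardize=False)
        assert np.allclose(rdm.matrix, 0.0)

    def test_missing_feature_rejected(self):
        stim = _stim_table(2).drop(columns="contrast")
        with pytest.raises(ValueError):
            lowlevel_model_rdm(stim)

    def test_permutation_equivariance(self):
        stim = _stim_table(4, seed=3)
        rdm = lowlevel_model_rdm(stim)
        perm = np.random.default_rng(0).permutation(8)
        rdm_perm = lowlevel_model_rdm(stim.iloc[perm].reset_index(drop=True))
        np.testing.assert_allclose(rdm_perm.matrix, rdm.matrix[np.ix_(perm, perm)])

    def test_category_model_values_and_counts(self):
        stim = _stim_table(10)
        rdm = category_model_rdm(stim)
        low = rdm.lower_triangle()
        assert set(np.unique(low)) == {0.5, 1.0}
        # 2 * C(10,2) = 90 within-category pairs, 10*10 = 100 between
        assert int((low == 0.5).sum()) == 90
        assert int((low == 1.0).sum()) == 100
        assert len(low) == 190


class TestNeuralRDM:
    def test_pair_count_for_20_stimuli(self, epochs_factory):
        ep, _ = epochs_factory(repetitions=4, seed=1, n_channels=8, fs=100.0, window=(-100.0, 100.0))
        rdms = neural_rdm_series(ep, cv_folds=2, seed=0)
        assert rdms.matrices.shape[1:] == (20, 20)
        assert rdms.lower_triangles().shape[1] == 190

    def test_identical_distributions_decode_at_chance(self, rng):
        """Two stimuli drawn from one response distribution: accuracy ~ 0.5."""
        from empadecode.containers import EpochSet

        data = rng.standard_normal((32, 8, 20))
        meta = pd.DataFrame(
            {
                "subject_id": 0,
                "group": "low-ALT",
                "task": "CE",
                "stimulus_id": np.repeat([1, 2], 16),
                "category": "positive",
            }
        )
        ep = EpochSet(data, 100.0, np.arange(20) * 10.0, [f"c{i}" for i in range(8)], meta)
        rdms = neural_rdm_series(ep, cv_folds=4, seed=0)
        assert abs(rdms.matrices[:, 0, 1].mean() - 0.5) < 0.1

    def test_separated_pair_decodes_high(self, rng):
        from empadecode.containers import EpochSet

        data = rng.standard_normal((32, 8, 10))
        data[16:, :, :] += 5.0  # mean separation 5x noise
        meta = pd.DataFrame(
            {
                "subject_id": 0,
                "group": "low-ALT",
                "task": "CE",
                "stimulus_id": np.repeat([1, 2], 16),
                "category": "positive",
            }
        )
        ep = EpochSet(data, 100.0, np.arange(10) * 10.0, [f"c{i}" for i in range(8)], meta)
        rdms = neural_rdm_series(ep, cv_folds=4, seed=0)
        assert rdms.matrices[:, 0, 1].mean() > 0.9

    def test_too_few_trials_per_stimulus_rejected(self, epochs_factory):
        ep, _ = epochs_factory(repetitions=2, seed=1, n_channels=8, fs=100.0, window=(-100.0, 100.0))
        with pytest.raises(ValueError):
            neural_rdm_series(ep, cv_folds=4, seed=0)

    def test_batched_lda_matches_sklearn_at_fixed_shrinkage(self, rng):
        """The vectorized shrinkage-LDA reproduces sklearn's lsqr solver."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X_tr_a = rng.standard_normal((12, 6, 4))
        X_tr_b = rng.standard_normal((12, 6, 4)) + 0.8
        X_te_a = rng.standard_normal((6, 6, 4))
        X_te_b = rng.standard_normal((6, 6, 4)) + 0.8
        alpha = 0.3
        correct = _lda_fold_accuracy(X_tr_a, X_tr_b, X_te_a, X_te_b, shrinkage=alpha)
        for t in range(4):
            X = np.concatenate([X_tr_a[:, :, t], X_tr_b[:, :, t]])
            y = np.repeat([0, 1], 12)
            clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=alpha).fit(X, y)
            pred_a = clf.predict(X_te_a[:, :, t])
            pred_b = clf.predict(X_te_b[:, :, t])
            sk_correct = (pred_a == 0).sum() + (pred_b == 1).sum()
            assert sk_correct == correct[t]

    def test_auto_shrinkage_matches_sklearn_ledoit_wolf(self, rng):
        from sklearn.covariance import ledoit_wolf_shrinkage

        X = rng.standard_normal((10, 7, 3))
        Xc = X - X.mean(axis=0)
        S_sum = np.einsum("nct,ndt->tcd", Xc, Xc)
        mine = _lw_shrinkage_batched(Xc, S_sum)
        for t in range(3):
            ref = ledoit_wolf_shrinkage(Xc[:, :, t], assume_centered=True)
            assert mine[t] == pytest.approx(ref, rel=1e-10)


class TestRsaTimecourse:
    def _series_from_model(self, model, times=np.arange(5) * 10.0):
        mats = np.repeat(model.matrix[None], len(times), axis=0)
        return RDMSeries(times, mats, model.stimulus_ids)

    def test_self_correlation_is_one(self):
        stim = _stim_table(5, seed=2)
        model = lowlevel_model_rdm(stim)
        tc = rsa_timecourse(self._series_from_model(model), model)
        np.testing.assert_allclose(tc.values, 1.0)

    def test_rank_reversal_is_minus_one(self):
        stim = _stim_table(5, seed=2)
        model = lowlevel_model_rdm(stim)
        reversed_mat = model.matrix.max() - model.matrix
        np.fill_diagonal(reversed_mat, 0.0)
        neural = self._series_from_model(ModelRDM(reversed_mat, model.stimulus_ids, "lowlevel"))
        tc = rsa_timecourse(neural, model)
        np.testing.assert_allclose(tc.values, -1.0)

    def test_ties_match_average_rank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 1.5, 2.0])
        y = np.array([1.0, 3.0, 2.0, 4.0, 2.0, 2.5])
        assert spearman_to_model(x[None, :], y)[0] == pytest.approx(spearman_oracle(x, y))
        from scipy.stats import spearmanr

        assert spearman_to_model(x[None, :], y)[0] == pytest.approx(spearmanr(x, y).statistic)

    def test_monotone_transform_invariance(self):
        stim = _stim_table(5, seed=4)
        model = lowlevel_model_rdm(stim)
        neural = self._series_from_model(model)
        warped = ModelRDM(np.sqrt(model.matrix), model.stimulus_ids, "lowlevel")
        a = rsa_timecourse(neural, model).values
        b = rsa_timecourse(neural, warped).values
        np.testing.assert_allclose(a, b)

    def test_joint_relabeling_invariance(self, rng):
        stim = _stim_table(5, seed=5)
        model = lowlevel_model_rdm(stim)
        mats = rng.uniform(0.3, 0.9, size=(4, 10, 10))
        mats = (mats + mats.transpose(0, 2, 1)) / 2
        neural = RDMSeries(np.arange(4) * 10.0, mats, model.stimulus_ids)
        base = rsa_timecourse(neural, model).values
        perm = rng.permutation(10)
        neural_p = RDMSeries(
            neural.times, mats[:, np.ix_(perm, perm)[0], np.ix_(perm, perm)[1]],
            model.stimulus_ids[perm],
        )
        model_p = ModelRDM(model.matrix[np.ix_(perm, perm)], model.stimulus_ids[perm], "lowlevel")
        np.testing.assert_allclose(rsa_timecourse(neural_p, model_p).values, base, atol=1e-12)

    def test_constant_vector_yields_nan_with_warning(self):
        stim = _stim_table(3, seed=6)
        model = lowlevel_model_rdm(stim)
        mats = np.full((2, 6, 6), 0.5)
        for m in mats:
            np.fill_diagonal(m, 0.0)
        neural = RDMSeries(np.arange(2) * 10.0, mats, model.stimulus_ids)
        with pytest.warns(UserWarning):
            tc = rsa_timecourse(neural, model)
        assert np.isnan(tc.values).all()
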