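import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.svm import SVC

from gcdmap.classify import (FeatureTable, _fit_svm_gram, build_feature_table,
                             fold_seeds, nested_cv_classify, pca_reduce,
                             permutation_test, relief_select, relief_weights,
                             roc_metrics, svm_rfe_rank, voxelwise_accuracy_map)


def two_class_labels(n_per_group):
    return np.array(["substate_A"] * n_per_group + ["substate_B"] * n_per_group)


class TestInternalSvm:
    @pytest.mark.parametrize("trial", range(5))
    def test_gram_fit_matches_public_svc_decisions(self, trial):
        rng = np.random.default_rng(trial)
        X = rng.normal(size=(24, 15))
        y = (rng.random(24) > 0.5).astype(float)
        if len(np.unique(y)) < 2:
            y[:3] = [0, 1, 0]
        K = X @ X.T
        alpha, b = _fit_svm_gram(K, y)
        ours = X @ (X.T @ alpha) + b
        ref = SVC(kernel="linear", C=1.0).fit(X, y).decision_function(X)
        np.testing.assert_allclose(ours, ref, atol=1e-6)


class TestVoxelwiseAccuracyMap:
    def _grid_args(self, V):
        voxel_index = np.column_stack([np.arange(V), np.zeros(V, int), np.zeros(V, int)])
        return voxel_index, (V, 1, 1)

    def test_uninformative_voxel_near_chance(self, rng):
        n = 10
        X = np.tile(rng.normal(size=(1, 8)), (2 * n, 1))  # identical across classes
        X += rng.normal(scale=1e-6, size=X.shape)
        vi, shape = self._grid_args(8)
        amap = voxelwise_accuracy_map(X, two_class_labels(n), vi, shape)
        assert (amap.accuracy_pct <= 65).all()
        assert amap.clusters == []

    def test_separated_voxels_reach_100_and_form_cluster(self, rng):
        n = 10
        X = rng.normal(size=(2 * n, 8))
        X[n:, :5] += 6.0  # class means +/-3 at sd ~1 on 5 contiguous voxels
        vi, shape = self._grid_args(8)
        amap = voxelwise_accuracy_map(X, two_class_labels(n), vi, shape)
        assert (amap.accuracy_pct[:5] == 100.0).all()
        assert len(amap.clusters) == 1
        assert amap.clusters[0]["size"] == 5
        assert amap.clusters[0]["peak_accuracy_pct"] == 100.0

    def test_four_contiguous_voxels_not_reported(self, rng):
        n = 10
        X = rng.normal(size=(2 * n, 9))
        X[n:, :4] += 6.0
        vi, shape = self._grid_args(9)
        amap = voxelwise_accuracy_map(X, two_class_labels(n), vi, shape)
        assert amap.clusters == []

    def test_cluster_respects_connectivity(self, rng):
        # two supra-threshold blocks touching only at a corner: separate under
        # 6-connectivity, merged under 26-connectivity
        n = 10
        grid = (4, 4, 1)
        coords = np.array([[i, j, 0] for i in range(4) for j in range(4)])
        hot = [(0, 0), (0, 1), (1, 0), (1, 1), (2, 2), (2, 3), (3, 2), (3, 3)]
        hot_rows = [k for k, (i, j, _) in enumerate(coords) if (i, j) in hot]
        X = rng.normal(size=(2 * n, len(coords)))
        X[n:, hot_rows] += 6.0
        labels = two_class_labels(n)
        amap6 = voxelwise_accuracy_map(X, labels, coords, grid, min_extent=4,
                                       connectivity=6)
        amap26 = voxelwise_accuracy_map(X, labels, coords, grid, min_extent=4,
                                        connectivity=26)
        assert len(amap6.clusters) == 2
        assert len(amap26.clusters) == 1

    def test_single_class_rejected(self, rng):
        vi, shape = self._grid_args(3)
        with pytest.raises(ValueError):
            voxelwise_accuracy_map(rng.normal(size=(8, 3)),
                                   np.array(["substate_A"] * 8), vi, shape)

    def test_tiny_class_rejected(self, rng):
        vi, shape = self._grid_args(3)
        labels = np.array(["substate_A"] * 3 + ["substate_B"] * 8)
        with pytest.raises(ValueError, match="4 subjects"):
            voxelwise_accuracy_map(rng.normal(size=(11, 3)), labels, vi, shape)


class TestPcaReduce:
    def _table(self, X, labels):
        return FeatureTable(X, [("m", i) for i in range(X.shape[1])], labels)

    def test_one_dimensional_features_unchanged(self, rng):
        X = rng.normal(size=(10, 1))
        table = self._table(X, two_class_labels(5))
        out, transform = pca_reduce(table)
        np.testing.assert_array_equal(out.matrix, X)

    def test_rank_two_data_keeps_at_most_two_components(self, rng):
        basis = rng.normal(size=(2, 30))
        X = rng.normal(size=(12, 2)) @ basis
        out, _ = pca_reduce(self._table(X, two_class_labels(6)), variance_kept=0.999)
        assert out.n_features <= 2

    def test_reconstruction_error_decreases_with_components(self, rng):
        X = rng.normal(size=(20, 100))
        Xc = X - X.mean(axis=0)
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        errors = []
        for k in (1, 5, 10, 15):
            recon = (Xc @ vt[:k].T) @ vt[:k]
            errors.append(np.linalg.norm(Xc - recon))
        assert all(a > b for a, b in zip(errors, errors[1:]))
        out, _ = pca_reduce(self._table(X, two_class_labels(10)), variance_kept=0.95)
        assert out.n_features <= min(X.shape)

    def test_transform_applies_to_held_out_rows(self, rng):
        X = rng.normal(size=(14, 20))
        out, transform = pca_reduce(self._table(X[:10], two_class_labels(5)))
        proj = transform(X[10:])
        assert proj.shape == (4, out.n_features)


class TestReliefSelect:
    def _table(self, X, labels):
        return FeatureTable(X, [("m", i) for i in range(X.shape[1])], labels)

    def test_planted_feature_gets_top_weight(self, rng):
        n = 15
        X = rng.normal(size=(2 * n, 30))
        X[n:, 7] += 4.0
        y01 = np.r_[np.zeros(n), np.ones(n)]
        w = relief_weights(X, y01)
        assert np.argmax(w) == 7

    def test_shuffled_labels_center_weights_near_zero(self, rng):
        n = 15
        X = rng.normal(size=(2 * n, 40))
        X[n:, 3] += 4.0
        y01 = rng.permutation(np.r_[np.zeros(n), np.ones(n)])
        w = relief_weights(X, y01)
        assert abs(np.median(w)) < 0.1

    def test_keep_all_is_identity(self, rng):
        X = rng.normal(size=(12, 9))
        table = self._table(X, two_class_labels(6))
        out = relief_select(table, k_keep=9)
        np.testing.assert_array_equal(out.matrix, X)
        assert out.feature_origin == table.feature_origin

    def test_k_above_feature_count_rejected(self, rng):
        table = self._table(rng.normal(size=(12, 5)), two_class_labels(6))
        with pytest.raises(ValueError, match="k_keep"):
            relief_select(table, k_keep=6)


class TestSvmRfe:
    def test_informative_feature_ranked_first(self, rng):
        n = 20
        X = rng.normal(size=(2 * n, 2))
        y01 = np.r_[np.zeros(n), np.ones(n)]
        X[n:, 0] += 3.0  # feature 0 informative, feature 1 noise
        ranking = svm_rfe_rank(X, y01)
        assert ranking[0] == 0

    def test_duplicated_columns_tie_broken_by_index(self, rng):
        n = 12
        base = rng.normal(size=(2 * n, 1))
        y01 = np.r_[np.zeros(n), np.ones(n)]
        X = np.hstack([base, base.copy(), rng.normal(size=(2 * n, 1))])
        ranking = svm_rfe_rank(X, y01)
        assert list(ranking).index(0) < list(ranking).index(1)

    def test_ranking_is_permutation(self, rng):
        X = rng.normal(size=(16, 23))
        y01 = np.r_[np.zeros(8), np.ones(8)]
        ranking = svm_rfe_rank(X, y01, elimination_fraction=0.3)
        assert sorted(ranking) == list(range(23))

    def test_non_finite_features_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0], [0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="finite"):
            svm_rfe_rank(X, np.array([0.0, 1.0, 0.0, 1.0]))


def separable_arrays(rng, n=20, V=50, shift=3.0, metrics=("inflow", "outflow", "intflow")):
    arrays = {m: rng.normal(size=(2 * n, V)) for m in metrics}
    for m in ("inflow", "outflow"):
        if m in arrays:
            arrays[m][n:, :5] += shift
    return arrays


class TestNestedCv:
    def test_separable_cohort_classified_well(self, rng):
        arrays = separable_arrays(rng)
        ft = build_feature_table(arrays, two_class_labels(20),
                                 ("inflow", "outflow", "intflow"))
        rep = nested_cv_classify(ft, seed=3, rfe_step=0.5)
        assert rep.auc >= 0.95
        assert rep.accuracy_pct >= 90.0

    def test_shuffled_labels_near_chance(self, rng):
        arrays = separable_arrays(rng)
        labels = np.random.default_rng(0).permutation(two_class_labels(20))
        ft = build_feature_table(arrays, labels, ("inflow", "outflow", "intflow"))
        rep = nested_cv_classify(ft, seed=3, rfe_step=0.5)
        assert 35.0 <= rep.accuracy_pct <= 65.0

    def test_combination_beats_single_metric_on_additive_signal(self, rng):
        # inflow and outflow carry independent planted signal of equal strength
        n, V = 20, 40
        arrays = {m: rng.normal(size=(2 * n, V)) for m in ("inflow", "outflow")}
        arrays["inflow"][n:, :6] += 1.0
        arrays["outflow"][n:, 6:12] += 1.0
        labels = two_class_labels(n)
        single_aucs = []
        for m in ("inflow", "outflow"):
            ft = build_feature_table(arrays, labels, (m,))
            single_aucs.append(nested_cv_classify(ft, seed=5, rfe_step=0.5).auc)
        ft2 = build_feature_table(arrays, labels, ("inflow", "outflow"))
        combined = nested_cv_classify(ft2, seed=5, rfe_step=0.5).auc
        assert combined >= max(single_aucs)

    def test_class_smaller_than_fold_count_reported(self, rng):
        X = rng.normal(size=(8, 10))
        labels = np.array(["substate_A"] * 4 + ["substate_B"] * 4)
        ft = FeatureTable(X, [("m", i) for i in range(10)], labels)
        with pytest.raises(ValueError, match="stratification"):
            nested_cv_classify(ft, n_outer=5)

    def test_report_reproducible_from_seed(self, rng):
        arrays = separable_arrays(rng, n=10, V=20, shift=1.0)
        ft = build_feature_table(arrays, two_class_labels(10),
                                 ("inflow", "outflow", "intflow"))
        a = nested_cv_classify(ft, seed=11, rfe_step=0.5)
        b = nested_cv_classify(ft, seed=11, rfe_step=0.5)
        assert a.auc == b.auc and a.accuracy_pct == b.accuracy_pct
        np.testing.assert_array_equal(a.pooled_decisions, b.pooled_decisions)
        assert [r["n_features"] for r in a.fold_records] == \
               [r["n_features"] for r in b.fold_records]

    def test_rate_identity_on_pooled_records(self, rng):
        arrays = separable_arrays(rng, n=10, V=20, shift=1.0)
        ft = build_feature_table(arrays, two_class_labels(10),
                                 ("inflow", "outflow", "intflow"))
        rep = nested_cv_classify(ft, seed=2, rfe_step=0.5)
        truth = rep.pooled_truth
        n_pos, n_neg = float((truth == 1).sum()), float((truth == 0).sum())
        expected = (rep.sensitivity_pct * n_pos + rep.specificity_pct * n_neg) / (n_pos + n_neg)
        assert rep.accuracy_pct == pytest.approx(expected, abs=1e-9)

    def test_no_leak_from_test_only_discriminative_feature(self, rng):
        """A feature discriminative only on one outer fold's test rows must
        leave that fold's inner selection untouched."""
        n = 10
        X = rng.normal(size=(2 * n, 30))
        labels = two_class_labels(n)
        ft0 = FeatureTable(X.copy(), [("m", i) for i in range(30)], labels)
        seed = 4
        # reconstruct the fold assignment the classifier will use
        from sklearn.model_selection import StratifiedKFold
        y01 = (labels == "substate_B").astype(float)
        fseed = fold_seeds(seed, 1)[0]
        outer = StratifiedKFold(5, shuffle=True, random_state=fseed)
        tr0, te0 = next(iter(outer.split(X, y01)))
        X_leak = X.copy()
        X_leak[te0, 0] = np.where(y01[te0] == 1, 10.0, -10.0)
        ft1 = FeatureTable(X_leak, [("m", i) for i in range(30)], labels)
        rep0 = nested_cv_classify(ft0, seed=seed, n_repeats=1, rfe_step=0.5)
        rep1 = nested_cv_classify(ft1, seed=seed, n_repeats=1, rfe_step=0.5)
        # fold 0 trains on rows where the injected feature is pure noise
        assert rep0.fold_records[0]["inner_best_accuracy"] == \
               rep1.fold_records[0]["inner_best_accuracy"]
        assert rep0.fold_records[0]["n_features"] == rep1.fold_records[0]["n_features"]
        np.testing.assert_array_equal(rep0.fold_records[0]["selected_features"],
                                      rep1.fold_records[0]["selected_features"])


class TestPermutationTest:
    def test_separable_cohort_minimum_p(self, rng):
        arrays = separable_arrays(rng, n=8, V=10, shift=6.0)
        ft = build_feature_table(arrays, two_class_labels(8),
                                 ("inflow", "outflow", "intflow"))
        obs = nested_cv_classify(ft, seed=1, n_outer=4, n_repeats=1, rfe_step=0.5)
        p, perm_acc = permutation_test(ft, n_perm=19, seed=1, observed=obs,
                                       n_outer=4, n_repeats=1, rfe_step=0.5)
        assert p == pytest.approx(1.0 / 20.0)
        assert len(perm_acc) == 19

    def test_noise_cohort_large_p(self, rng):
        arrays = {m: rng.normal(size=(16, 10)) for m in ("inflow",)}
        ft = build_feature_table(arrays, two_class_labels(8), ("inflow",))
        obs = nested_cv_classify(ft, seed=2, n_outer=4, n_repeats=1, rfe_step=0.5)
        p, _ = permutation_test(ft, n_perm=19, seed=2, observed=obs,
                                n_outer=4, n_repeats=1, rfe_step=0.5)
        assert p > 0.05

    def test_zero_permutations_rejected(self, rng):
        arrays = {"inflow": rng.normal(size=(16, 5))}
        ft = build_feature_table(arrays, two_class_labels(8), ("inflow",))
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(ft, n_perm=0)


class TestRocMetrics:
    def test_perfectly_ordered_auc_one(self):
        labels = np.array([0, 0, 0, 1, 1, 1])
        auc, acc, sens, spec = roc_metrics(np.array([-3, -2, -1, 1, 2, 3.0]), labels)
        assert auc == 1.0 and acc == 100.0 and sens == 100.0 and spec == 100.0

    def test_anti_ordered_auc_zero(self):
        labels = np.array([0, 0, 1, 1])
        auc, _, _, _ = roc_metrics(np.array([2.0, 1.0, -1.0, -2.0]), labels)
        assert auc == 0.0

    def test_random_decisions_auc_half(self, rng):
        labels = np.r_[np.zeros(1000), np.ones(1000)]
        auc, _, _, _ = roc_metrics(rng.normal(size=2000), labels)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_constant_decisions_warn_and_return_half(self):
        labels = np.array([0, 0, 1, 1])
        with pytest.warns(UserWarning, match="constant"):
            auc, _, _, _ = roc_metrics(np.ones(4), labels)
        assert auc == 0.5

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_auc_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        dec = r.normal(size=30)
        labels = np.r_[np.zeros(15), np.ones(15)]
        auc1, _, _, _ = roc_metrics(dec, labels)
        auc2, _, _, _ = roc_metrics(np.exp(2.0 * dec) + 5.0, labels)
        assert auc1 == pytest.approx(auc2, abs=1e-12)
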