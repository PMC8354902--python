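"""Site correction, balanced accuracy, nested CV, permutation inference."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import balanced_accuracy_score

import taskconn as tc
from taskconn.classify import CVConfig, rank_weights, subsampling_curve
from taskconn.cohort import ModuleAssignment
from taskconn.measures import FeatureTable


def make_table(X, groups, sites=None, tag="tonic_strength"):
    n, p = X.shape
    sids = [f"sub-{i:03d}" for i in range(1, n + 1)]
    data = pd.DataFrame(X, index=sids,
                        columns=[f"n{j}" for j in range(p)])
    groups = pd.Series(list(groups), index=sids)
    sites = pd.Series(list(sites) if sites is not None else "siteA",
                      index=sids)
    return FeatureTable(data, tag, groups, sites)


class TestSiteCorrect:
    def test_single_site_centers_columns(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5.0, 1.0, size=(10, 3))
        tab = make_table(X, ["BPD"] * 5 + ["NPC"] * 5)
        out = tc.site_correct(tab)
        np.testing.assert_allclose(out.matrix, X - X.mean(0), atol=1e-10)

    def test_site_indicator_feature_becomes_zero(self):
        sites = ["a"] * 6 + ["b"] * 6
        X = np.array([[1.0 if s == "a" else 0.0] for s in sites])
        tab = make_table(X, ["BPD", "NPC"] * 6, sites)
        out = tc.site_correct(tab)
        assert np.max(np.abs(out.matrix)) < 1e-10

    def test_per_site_means_zero(self):
        rng = np.random.default_rng(1)
        sites = ["a"] * 7 + ["b"] * 9
        X = rng.normal(size=(16, 4)) + np.where(
            np.array(sites) == "a", 1.0, 3.0)[:, None]
        tab = make_table(X, ["BPD", "NPC"] * 8, sites)
        out = tc.site_correct(tab)
        for s in ("a", "b"):
            sel = out.sites == s
            np.testing.assert_allclose(out.matrix[sel.to_numpy()].mean(0),
                                       0.0, atol=1e-10)

    def test_single_subject_site_warns(self):
        X = np.random.default_rng(2).normal(size=(5, 2))
        tab = make_table(X, ["BPD", "NPC", "BPD", "NPC", "BPD"],
                         ["a", "a", "a", "a", "b"])
        with pytest.warns(UserWarning, match="single subject"):
            tc.site_correct(tab)


class TestBalancedAccuracy:
    def test_examples(self):
        assert tc.balanced_accuracy([1, 1, 0, 0], [1, 1, 0, 0]) == 1.0
        assert tc.balanced_accuracy([1, 1, 0, 0], [1, 0, 0, 0]) == 0.75
        assert tc.balanced_accuracy([1, 1, 0, 0], [1, 1, 1, 1]) == 0.5

    def test_one_class_truth_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            tc.balanced_accuracy([1, 1, 1], [1, 0, 1])

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            y = rng.integers(0, 2, size=30)
            if len(np.unique(y)) < 2:
                continue
            yp = rng.integers(0, 2, size=30)
            assert tc.balanced_accuracy(y, yp) == pytest.approx(
                balanced_accuracy_score(y, yp))


def random_models(n=40, p=6, n_models=3, seed=0, planted_tag=None):
    rng = np.random.default_rng(seed)
    y = np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
    groups = np.where(y == 1, "BPD", "NPC")
    models = {}
    for m in range(n_models):
        tag = f"model_{m}"
        X = rng.normal(size=(n, p))
        models[tag] = make_table(X, groups, tag=tag)
    if planted_tag:
        X = rng.normal(size=(n, p))
        X[:, 0] += 10.0 * y  # perfectly separating feature
        models[planted_tag] = make_table(X, groups, tag=planted_tag)
    return models, y


class TestNestedCV:
    CFG = CVConfig(outer_folds=5, inner_folds=3, repetitions=5, seed=0)

    def test_chance_level_on_null_features(self):
        models, y = random_models(seed=1)
        cfg = CVConfig(outer_folds=5, inner_folds=3, repetitions=20, seed=0)
        res = tc.nested_cv_classify(models, y, cfg)
        assert 0.40 <= res.mean_balanced_accuracy <= 0.60

    def test_perfect_feature_dominates(self):
        models, y = random_models(seed=2, planted_tag="winner")
        res = tc.nested_cv_classify(models, y, self.CFG)
        assert res.model_selection_counts["winner"] >= 0.9
        assert res.mean_balanced_accuracy >= 0.95

    def test_deterministic_given_seed(self):
        models, y = random_models(seed=3)
        a = tc.nested_cv_classify(models, y, self.CFG)
        b = tc.nested_cv_classify(models, y, self.CFG)
        np.testing.assert_array_equal(a.balanced_accuracies,
                                      b.balanced_accuracies)
        for fa, fb in zip(a.fold_log, b.fold_log):
            for va, vb in zip(fa, fb):
                np.testing.assert_array_equal(va, vb)

    def test_validation_folds_partition_subjects(self):
        models, y = random_models(seed=4)
        res = tc.nested_cv_classify(models, y, self.CFG)
        for rep_folds in res.fold_log:
            allv = np.concatenate(rep_folds)
            assert len(allv) == len(y)
            assert len(np.unique(allv)) == len(y)

    def test_selection_proportions_sum_to_one(self):
        models, y = random_models(seed=5)
        res = tc.nested_cv_classify(models, y, self.CFG)
        assert sum(res.model_selection_counts.values()) == pytest.approx(1.0)
        assert all(0 <= v <= 1 for v in res.balanced_accuracies)
        assert res.ci_lower <= res.mean_balanced_accuracy <= res.ci_upper

    def test_too_many_folds_suggests_fewer(self):
        models, y = random_models(n=10, seed=6)
        with pytest.raises(ValueError, match="fewer folds|folds"):
            tc.nested_cv_classify(models, y, CVConfig(outer_folds=10,
                                                      inner_folds=5,
                                                      repetitions=1))


class TestPermutationTest:
    def test_p_floor(self):
        models, y = random_models(seed=7, planted_tag="winner")
        cfg = CVConfig(outer_folds=3, inner_folds=2, repetitions=1,
                       n_permutations=20, seed=0)
        out = tc.permutation_test(models, y, cfg)
        assert out.p_value >= 1.0 / 20

    def test_observed_below_null_median_gives_large_p(self):
        models, y = random_models(seed=8)
        cfg = CVConfig(outer_folds=3, inner_folds=2, repetitions=1,
                       n_permutations=50, seed=1)
        out = tc.permutation_test(models, y, cfg, observed=0.1)
        assert out.p_value > 0.5

    def test_permuted_planted_signal_concentrates_at_chance(self):
        """Label permutation destroys a perfectly separating feature."""
        models, y = random_models(seed=9, planted_tag="winner", n_models=1)
        cfg = CVConfig(outer_folds=3, inner_folds=2, repetitions=1,
                       n_permutations=100, seed=2)
        out = tc.permutation_test(models, y, cfg, observed=1.0)
        assert 0.45 <= out.null_distribution.mean() <= 0.55


class TestRankWeights:
    def _result_with_weights(self, w, labels):
        from taskconn.classify import CVResult
        return CVResult(
            balanced_accuracies=np.array([0.5]),
            sensitivities=np.array([0.5]), specificities=np.array([0.5]),
            aucs=np.array([0.5]), mean_balanced_accuracy=0.5,
            ci_lower=0.5, ci_upper=0.5,
            model_selection_counts={"m": 1.0},
            inner_mean_balanced_accuracy={"m": 0.5},
            averaged_weights={"m": np.asarray(w)},
            feature_labels={"m": list(labels)}, fold_log=[])

    def test_sorted_by_absolute_weight_sign_retained(self):
        res = self._result_with_weights([0.1, -0.5, 0.2], ["a", "b", "c"])
        ranked = rank_weights(res, "m")
        assert [r[0] for r in ranked] == ["b", "c", "a"]
        assert ranked[0][1] == -0.5
        assert [r[2] for r in ranked] == [1, 2, 3]

    def test_ties_stable_by_node_order(self):
        res = self._result_with_weights([0.3, -0.3, 0.3], ["a", "b", "c"])
        assert [r[0] for r in rank_weights(res, "m")] == ["a", "b", "c"]

    def test_never_selected_model_errors(self):
        res = self._result_with_weights([1.0], ["a"])
        with pytest.raises(KeyError, match="never won"):
            rank_weights(res, "other")


class TestModuleGroupTest:
    MODS = ModuleAssignment({"n0": "emotion", "n1": "emotion",
                             "n2": "other"})

    def test_identical_distributions_give_zero_d(self):
        X = np.tile(np.random.default_rng(0).normal(size=(5, 3)), (2, 1))
        tab = make_table(X, ["BPD"] * 5 + ["NPC"] * 5)
        out = tc.module_group_test(tab, self.MODS, ("BPD", "NPC"))
        np.testing.assert_allclose(out["cohens_d"], 0.0, atol=1e-12)

    def test_unit_shift_gives_d_near_one(self):
        rng = np.random.default_rng(1)
        X = np.r_[rng.normal(1.0, 1.0, size=(200, 3)),
                  rng.normal(0.0, 1.0, size=(200, 3))]
        tab = make_table(X, ["BPD"] * 200 + ["NPC"] * 200)
        out = tc.module_group_test(tab, self.MODS, ("BPD", "NPC"))
        # single-node module: d estimates the unit shift directly
        assert 0.8 <= out.loc["other", "cohens_d"] <= 1.2
        # two-node module of i.i.d. features: averaging halves the
        # variance, so d is inflated by sqrt(2)
        assert 1.2 <= out.loc["emotion", "cohens_d"] <= 1.6

    def test_single_node_module_reduces_to_node_test(self):
        from scipy import stats
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 3))
        tab = make_table(X, ["BPD"] * 15 + ["NPC"] * 15)
        out = tc.module_group_test(tab, self.MODS, ("BPD", "NPC"))
        t, p = stats.ttest_ind(X[:15, 2], X[15:, 2], equal_var=False)
        assert out.loc["other", "t"] == pytest.approx(t)
        assert out.loc["other", "p"] == pytest.approx(p)

    def test_empty_module_errors(self):
        X = np.random.default_rng(3).normal(size=(10, 1))
        tab = make_table(X, ["BPD"] * 5 + ["NPC"] * 5)
        mods = ModuleAssignment({"n0": "emotion", "zz": "motivation"})
        with pytest.raises(ValueError, match="motivation"):
            tc.module_group_test(tab, mods, ("BPD", "NPC"))


class TestSubsampling:
    def test_full_size_equals_plain_estimate(self):
        models, y = random_models(seed=10)
        cfg = CVConfig(outer_folds=5, inner_folds=3, repetitions=3, seed=4)
        curve = subsampling_curve(models, y, [len(y)], cfg)
        plain = tc.nested_cv_classify(models, y, cfg)
        assert curve.loc[len(y), "mean_balanced_accuracy"] == pytest.approx(
            plain.mean_balanced_accuracy)

    def test_oversized_subsample_errors(self):
        models, y = random_models(seed=11)
        with pytest.raises(ValueError, match="exceeds"):
            subsampling_curve(models, y, [100],
                              CVConfig(outer_folds=3, inner_folds=2,
                                       repetitions=1))
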