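from itertools import combinations

import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from tfnbs import (
    ConnectomeSVMClassifier,
    classification_metrics,
    feature_stability,
    loocv_classify,
    rfe_select,
    select_features_fold,
    tune_svm,
)


def _edge_data(seed=0, n_per_class=12, effect_edges=(), effect=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per_class, 153)) + 5.0
    for k in effect_edges:
        X[n_per_class:, k] += effect
    y = np.array(["PD"] * n_per_class + ["MSA"] * n_per_class)
    return X, y


class TestMetrics:
    def test_published_recalls_reproduce_accuracy_cell(self):
        """22/31 MSA and 56/65 PD recalls give the published 0.79 accuracy."""
        y_true = np.array(["MSA"] * 31 + ["PD"] * 65)
        y_pred = np.array(
            ["MSA"] * 22 + ["PD"] * 9 + ["PD"] * 56 + ["MSA"] * 9
        )
        m = classification_metrics(y_true, y_pred, positive="MSA")
        assert m["sensitivity"] == pytest.approx(22 / 31, abs=5e-3)
        assert m["specificity"] == pytest.approx(56 / 65, abs=5e-3)
        assert round(m["balanced_accuracy"], 2) == 0.79

    def test_perfect_and_degenerate_patterns(self):
        y_true = np.array(["MSA", "MSA", "PD", "PD"])
        perfect = classification_metrics(y_true, y_true)
        assert all(v == 1.0 for v in perfect.values())
        inverted = classification_metrics(y_true, np.array(["PD", "PD", "PD", "PD"]))
        assert inverted["sensitivity"] == 0.0
        assert inverted["specificity"] == 1.0
        assert inverted["balanced_accuracy"] == 0.5

    def test_balanced_accuracy_is_mean_of_recalls(self):
        rng = np.random.default_rng(0)
        y_true = np.array(["MSA"] * 13 + ["PD"] * 29)
        y_pred = rng.choice(["MSA", "PD"], size=42)
        m = classification_metrics(y_true, y_pred)
        assert m["balanced_accuracy"] == (m["sensitivity"] + m["specificity"]) / 2

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(np.array(["MSA"] * 3), np.array(["MSA"] * 3))


class TestFeatureStability:
    def test_always_and_never_selected(self):
        freq = feature_stability([[0, 2], [0], [0, 1]], n_features=4)
        assert freq[0] == 1.0
        assert freq[3] == 0.0
        assert freq[1] == pytest.approx(1 / 3)

    def test_recount_oracle(self):
        rng = np.random.default_rng(1)
        folds = [sorted(rng.choice(10, size=rng.integers(1, 5), replace=False)) for _ in range(7)]
        freq = feature_stability([list(f) for f in folds], n_features=10)
        for k in range(10):
            assert freq[k] == sum(k in f for f in folds) / 7


class TestRfe:
    def test_single_feature_passes_through(self):
        X, y = _edge_data(seed=2)
        assert np.array_equal(rfe_select(X[:, :1], y), [0])

    def test_informative_feature_survives_noise(self):
        rng = np.random.default_rng(3)
        n = 30
        X = rng.normal(size=(2 * n, 12))
        X[n:, 4] += 3.0
        y = np.array(["PD"] * n + ["MSA"] * n)
        selected = rfe_select(X, y)
        assert 4 in selected

    def test_matches_exhaustive_best_subset_on_three_features(self):
        """With 3 features, RFE-with-CV must find a subset at least as good as
        exhaustive best-subset search (ties toward fewer features)."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(24, 3))
        X[12:, 0] += 2.0
        X[12:, 1] += 0.5
        y = np.array(["PD"] * 12 + ["MSA"] * 12)
        selected = rfe_select(X, y, inner_folds=5)
        cv = StratifiedKFold(n_splits=5)

        def score(cols):
            return cross_val_score(SVC(kernel="linear", C=1.0), X[:, cols], y, cv=cv).mean()

        best = max(
            (score(list(c)), -len(c), list(c))
            for r in (1, 2, 3)
            for c in combinations(range(3), r)
        )
        assert score(list(selected)) == pytest.approx(best[0])
        assert len(selected) <= -best[1]

    def test_single_class_rejected(self):
        X, _ = _edge_data(seed=5)
        with pytest.raises(ValueError):
            rfe_select(X[:4, :3], np.array(["PD"] * 4))


class TestTuneSvm:
    def test_separable_data_fits_perfectly(self):
        X, y = _edge_data(seed=6, effect_edges=(0,), effect=20.0)
        model, c = tune_svm(X[:, :2], y)
        assert (model.predict(X[:, :2]) == y).all()
        assert c in (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)

    def test_ties_resolve_to_smallest_c(self):
        X, y = _edge_data(seed=7, effect_edges=(0,), effect=50.0)
        _, c = tune_svm(X[:, :1], y, c_grid=(1e-2, 1.0, 1e2))
        assert c == 1e-2  # all Cs are perfect on separable data

    def test_chance_level_on_label_permuted_data(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 5))
        y = rng.permutation(np.array(["PD"] * 20 + ["MSA"] * 20))
        cv = StratifiedKFold(n_splits=5)
        score = cross_val_score(SVC(kernel="linear", C=1.0), X, y, cv=cv).mean()
        assert 0.2 <= score <= 0.8  # inside a generous chance band

    def test_empty_grid_rejected(self):
        X, y = _edge_data(seed=9)
        with pytest.raises(ValueError):
            tune_svm(X, y, c_grid=())


class TestNestedClassifier:
    def test_hugely_separated_edge_selected_every_fold(self):
        X, y = _edge_data(seed=10, n_per_class=10, effect_edges=(7,), effect=10.0)
        est = ConnectomeSVMClassifier(selection_permutations=99, random_state=0)
        report = loocv_classify(X, y, estimator=est)
        assert report.stability.iloc[7] == 1.0
        assert report.metrics["balanced_accuracy"] == 1.0

    def test_null_cohort_uses_fallback_and_stays_near_chance(self):
        X, y = _edge_data(seed=11, n_per_class=10)
        est = ConnectomeSVMClassifier(selection_permutations=99, k_fallback=5, random_state=0)
        report = loocv_classify(X, y, estimator=est)
        # binomial 95% band around 0.5 for 20 LOOCV predictions
        assert 0.1 <= report.metrics["balanced_accuracy"] <= 0.9
        assert all(len(f.candidate_features) == 5 for f in report.folds)

    def test_no_leakage_from_held_out_subject(self):
        """Corrupting the held-out subject's data must not change the fold."""
        X, y = _edge_data(seed=12, n_per_class=8, effect_edges=(3,), effect=2.0)
        est = ConnectomeSVMClassifier(selection_permutations=49, random_state=0)
        fit_a = est.fit(X[1:], y[1:], covariates=None)
        selected_a, c_a = fit_a.selected_.copy(), fit_a.best_c_
        coef_a = fit_a.svm_.coef_.copy()
        X_corrupted = X.copy()
        X_corrupted[0] = 1e9  # arbitrary garbage in the held-out row
        fit_b = ConnectomeSVMClassifier(selection_permutations=49, random_state=0).fit(
            X_corrupted[1:], y[1:], covariates=None
        )
        assert np.array_equal(selected_a, fit_b.selected_)
        assert c_a == fit_b.best_c_
        assert np.array_equal(coef_a, fit_b.svm_.coef_)

    def test_identical_seeds_identical_reports(self):
        X, y = _edge_data(seed=13, n_per_class=8, effect_edges=(0,), effect=1.5)
        est = ConnectomeSVMClassifier(selection_permutations=49, random_state=3)
        a = loocv_classify(X, y, estimator=est)
        b = loocv_classify(X, y, estimator=est)
        assert a.metrics == b.metrics
        assert [f.selected_features for f in a.folds] == [f.selected_features for f in b.folds]

    def test_select_features_fold_matches_estimator(self):
        X, y = _edge_data(seed=14, n_per_class=8, effect_edges=(5,), effect=8.0)
        est = ConnectomeSVMClassifier(selection_permutations=49, random_state=0)
        features = select_features_fold(X, y, estimator=est)
        assert 5 in features

    def test_single_subject_class_rejected(self):
        X, y = _edge_data(seed=15, n_per_class=2)
        with pytest.raises(ValueError):
            ConnectomeSVMClassifier(selection_permutations=9).fit(X[1:], y[1:])
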