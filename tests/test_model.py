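"""Fold construction, metrics, grid search, boosting and the Results object."""

import numpy as np
import pandas as pd
import pytest
from sklearn.svm import SVC

from epicog.boosting import SAMMERClassifier
from epicog.model import (
    CognitionClassifier,
    ModelConfig,
    compute_metrics,
    cross_validate,
    grid_search_fit,
    make_folds,
    small_grid,
)


class TestMakeFolds:
    def test_131_subjects_split_27_26_26_26_26(self):
        y = np.array([0] * 55 + [1] * 76)
        folds = make_folds(y, seed=3)
        sizes = sorted(len(te) for _, te in folds)
        assert sizes == [26, 26, 26, 26, 27]

    def test_test_folds_partition_index_set(self):
        y = np.repeat([0, 1], [20, 30])
        folds = make_folds(y, seed=0)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(50))

    def test_stratification_within_one_subject(self):
        y = np.array([0] * 55 + [1] * 76)
        for _, te in make_folds(y, seed=1):
            frac = (y[te] == 1).mean()
            assert abs((y[te] == 1).sum() - len(te) * 76 / 131) <= 1.0

    def test_same_seed_identical_assignment(self):
        y = np.repeat([0, 1], [20, 30])
        f1 = make_folds(y, seed=9)
        f2 = make_folds(y, seed=9)
        for (a, b), (c, d) in zip(f1, f2):
            np.testing.assert_array_equal(a, c)
            np.testing.assert_array_equal(b, d)

    def test_small_class_errors(self):
        with pytest.raises(ValueError):
            make_folds(np.array([0, 0, 0, 1, 1, 1, 1, 1, 1]), n_folds=5)


class TestComputeMetrics:
    def test_hand_confusion_matrix(self):
        # TP=3, FP=1, TN=5, FN=1
        y_true = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
        m = compute_metrics(y_true, y_pred, np.linspace(0, 1, 10))
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(0.75)

    def test_perfect_prediction_all_ones(self):
        y = np.array([0, 0, 1, 1])
        m = compute_metrics(y, y, y.astype(float))
        assert all(m[k] == 1.0 for k in ("accuracy", "precision", "recall", "f1", "auc"))

    def test_constant_scores_auc_half(self):
        m = compute_metrics([0, 1, 0, 1], [0, 1, 0, 1], [0.5] * 4)
        assert m["auc"] == pytest.approx(0.5)

    def test_undefined_precision_flagged_zero(self):
        m = compute_metrics([1, 1, 0], [0, 0, 0], [0.1, 0.2, 0.3])
        assert m["precision"] == 0.0 and m["precision_undefined"] == 1.0

    def test_label_swap_maps_auc_to_complement(self, rng):
        y = rng.integers(0, 2, 50)
        s = rng.uniform(0, 1, 50)
        a = compute_metrics(y, (s > 0.5).astype(int), s)["auc"]
        b = compute_metrics(1 - y, (s > 0.5).astype(int), s)["auc"]
        assert a == pytest.approx(1 - b)


def _separable(n=40):
    rng = np.random.default_rng(5)
    X = np.vstack([rng.normal(-3, 0.3, (n // 2, 2)), rng.normal(3, 0.3, (n // 2, 2))])
    y = np.repeat([0, 1], n // 2)
    return pd.DataFrame(X, columns=["a", "b"]), pd.Series(y)


class TestGridSearchFit:
    @pytest.mark.parametrize("algorithm", ["adaboost_svm", "gbdt"])
    def test_separable_data_training_accuracy_one(self, algorithm):
        X, y = _separable()
        cfg = ModelConfig(algorithm=algorithm, param_grid=small_grid(algorithm), seed=0)
        est, params = grid_search_fit(X.to_numpy(), y.to_numpy(), cfg)
        assert (est.predict(X.to_numpy()) == y.to_numpy()).mean() == 1.0
        assert set(params) == set(cfg.param_grid)

    def test_same_seed_same_choice(self):
        X, y = _separable()
        cfg = ModelConfig(algorithm="gbdt", param_grid=small_grid("gbdt"), seed=11)
        _, p1 = grid_search_fit(X.to_numpy(), y.to_numpy(), cfg)
        _, p2 = grid_search_fit(X.to_numpy(), y.to_numpy(), cfg)
        assert p1 == p2

    def test_empty_grid_errors(self):
        with pytest.raises(ValueError):
            ModelConfig(algorithm="gbdt", param_grid={"n_estimators": []})


class TestSammer:
    def test_boosting_improves_over_single_weak_svc(self):
        rng = np.random.default_rng(2)
        n = 120
        X = rng.uniform(-1, 1, (n, 2))
        y = ((X[:, 0] * X[:, 1]) > 0).astype(int)  # XOR-ish, needs nonlinearity
        clf = SAMMERClassifier(
            estimator=SVC(kernel="rbf", gamma=2.0, probability=True, random_state=0),
            n_estimators=10,
            random_state=0,
        ).fit(X, y)
        assert (clf.predict(X) == y).mean() > 0.9
        proba = clf.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_agrees_with_sklearn_discrete_adaboost_on_easy_data(self):
        """Cross-check: on well-separated data both boosting variants agree."""
        from sklearn.ensemble import AdaBoostClassifier
        from sklearn.tree import DecisionTreeClassifier

        X, y = _separable(60)
        X, y = X.to_numpy(), y.to_numpy()
        ours = SAMMERClassifier(
            estimator=SVC(kernel="rbf", probability=True, random_state=0),
            n_estimators=5,
            random_state=0,
        ).fit(X, y)
        theirs = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1), n_estimators=5, random_state=0
        ).fit(X, y)
        np.testing.assert_array_equal(ours.predict(X), theirs.predict(X))

    def test_invalid_learning_rate_errors(self):
        X, y = _separable(20)
        with pytest.raises(ValueError):
            SAMMERClassifier(estimator=SVC(probability=True), learning_rate=0.0).fit(
                X.to_numpy(), y.to_numpy()
            )


class TestCrossValidate:
    def test_mean_row_is_arithmetic_mean(self):
        X, y = _separable(50)
        cfg = ModelConfig(algorithm="gbdt", param_grid={k: [v[0]] for k, v in small_grid("gbdt").items()}, seed=0)
        res = cross_validate(X, y, cfg)
        np.testing.assert_allclose(res.mean_row.to_numpy(), res.per_fold.mean(axis=0).to_numpy(), atol=1e-12)

    def test_reproducible_report(self):
        X, y = _separable(50)
        cfg = ModelConfig(algorithm="gbdt", param_grid={k: [v[0]] for k, v in small_grid("gbdt").items()}, seed=4)
        r1 = cross_validate(X, y, cfg)
        r2 = cross_validate(X, y, cfg)
        pd.testing.assert_frame_equal(r1.per_fold, r2.per_fold)
        assert r1.chosen_hyperparameters == r2.chosen_hyperparameters

    def test_summary_and_save_roundtrip(self, tmp_path):
        X, y = _separable(50)
        cfg = ModelConfig(algorithm="gbdt", param_grid={k: [v[0]] for k, v in small_grid("gbdt").items()}, seed=0)
        res = cross_validate(X, y, cfg)
        text = res.summary()
        assert "Mean-value" in text and "Fold 5" in text
        res.save(tmp_path / "cv")
        assert (tmp_path / "cv.csv").exists() and (tmp_path / "cv.json").exists()


class TestCognitionClassifier:
    def test_top_k_restricts_feature_count(self, cohort_4040):
        feats, labels, _ = cohort_4040
        grid = {k: [v[0]] for k, v in small_grid("gbdt").items()}
        res = CognitionClassifier(feats, labels, algorithm="gbdt", top_k=15, param_grid=grid, seed=0).fit()
        assert res.n_features == 15
        assert res.ranking is not None and len(res.ranking.feature_names) == 684

    def test_from_dataframe_constructor(self, cohort_4040):
        feats, labels, _ = cohort_4040
        df = feats.copy()
        df["group"] = labels.map({0: "CON", 1: "CI"})
        clf = CognitionClassifier.from_dataframe(df, algorithm="gbdt", top_k=10)
        assert clf.table.shape[1] == 684
        assert set(clf.labels.unique()) == {0, 1}
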