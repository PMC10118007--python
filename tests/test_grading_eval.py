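import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dl_lasso.grading_eval import (
    confusion_metrics,
    evaluate_predictions,
    knn_predict,
    roc_auc,
    svm_train_predict,
)
from oracles import auc_concordance, knn_bruteforce


class TestKnn:
    def test_unanimous_neighborhood(self):
        train_X = np.r_[np.full((7, 1), 5.0) + np.arange(7)[:, None] * 0.01,
                        np.full((5, 1), -40.0)]
        train_y = np.r_[np.ones(7, dtype=int), np.zeros(5, dtype=int)]
        preds, scores = knn_predict(train_X, train_y, np.array([[5.0]]), K=7)
        assert preds[0] == 1 and scores[0] == 1.0

    def test_k1_returns_exact_match_label(self):
        train_X = np.array([[0.0], [1.0], [2.0]])
        train_y = np.array([1, 0, 1])
        preds, _ = knn_predict(train_X, train_y, np.array([[1.0]]), K=1)
        assert preds[0] == 0

    def test_even_k_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            knn_predict(np.zeros((4, 1)), np.array([0, 1, 0, 1]), np.zeros((1, 1)), K=2)

    def test_eight_point_toy_matches_bruteforce(self):
        offs = np.array([0.0, 0.1, 0.2, 0.3])
        train_X = np.r_[(-3.0 + offs), (3.0 + offs)][:, None]
        train_y = np.r_[np.zeros(4, dtype=int), np.ones(4, dtype=int)]
        test = np.array([[0.5]])
        preds, scores = knn_predict(train_X, train_y, test, K=7)
        exp_label, exp_frac = knn_bruteforce(train_X, train_y, test[0], K=7)
        assert preds[0] == exp_label
        assert scores[0] == pytest.approx(exp_frac)

    def test_distance_ties_resolve_to_lower_index(self):
        # two training points equidistant from the query; K=1 must take index 0
        train_X = np.array([[1.0], [-1.0], [5.0]])
        train_y = np.array([1, 0, 0])
        preds, _ = knn_predict(train_X, train_y, np.array([[0.0]]), K=1)
        assert preds[0] == 1


class TestSvm:
    def test_separable_toy_classifies_and_signs_scores(self):
        gen = np.random.default_rng(0)
        X0 = gen.normal(-4, 0.3, size=(15, 2))
        X1 = gen.normal(4, 0.3, size=(15, 2))
        train_X = np.vstack([X0, X1])
        train_y = np.r_[np.zeros(15, dtype=int), np.ones(15, dtype=int)]
        preds, scores, _ = svm_train_predict(train_X, train_y, np.array([[4.0, 4.0]]), seed=0)
        assert preds[0] == 1 and scores[0] > 0

    def test_deterministic_repeat(self):
        gen = np.random.default_rng(1)
        X = gen.standard_normal((24, 3))
        y = np.r_[np.zeros(12, dtype=int), np.ones(12, dtype=int)]
        out1 = svm_train_predict(X, y, X, seed=5)
        out2 = svm_train_predict(X, y, X, seed=5)
        np.testing.assert_array_equal(out1[0], out2[0])
        np.testing.assert_array_equal(out1[1], out2[1])
        assert out1[2] == out2[2]

    def test_rbf_solves_xor_where_linear_cannot(self):
        gen = np.random.default_rng(2)
        centers = np.array([[2, 2], [-2, -2], [2, -2], [-2, 2]], dtype=float)
        cluster_y = np.array([0, 0, 1, 1])
        Xtr = np.vstack([c + gen.normal(0, 0.4, size=(20, 2)) for c in centers])
        ytr = np.repeat(cluster_y, 20)
        Xte = np.vstack([c + gen.normal(0, 0.4, size=(10, 2)) for c in centers])
        yte = np.repeat(cluster_y, 10)
        preds_rbf, _, _ = svm_train_predict(Xtr, ytr, Xte, seed=0)
        rbf_acc = (preds_rbf == yte).mean()
        from sklearn.svm import SVC

        lin = SVC(kernel="linear", C=1.0).fit(Xtr, ytr)
        lin_acc = (lin.predict(Xte) == yte).mean()
        assert rbf_acc > 0.9
        assert lin_acc < 0.7

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            svm_train_predict(np.zeros((5, 2)), np.zeros(5, dtype=int), np.zeros((1, 2)))


class TestConfusionMetrics:
    def test_hand_computed_table(self):
        y_true = np.r_[np.ones(4, dtype=int), np.zeros(6, dtype=int)]
        y_pred = np.r_[np.ones(3, dtype=int), [0], [1], np.zeros(5, dtype=int)]
        counts, report = confusion_metrics(y_true, y_pred)
        assert (counts.TP, counts.FP, counts.FN, counts.TN) == (3, 1, 1, 5)
        assert report.recall == pytest.approx(0.75)
        assert report.precision == pytest.approx(0.75)
        assert report.f1 == pytest.approx(0.75)
        assert report.accuracy == pytest.approx(0.8)

    def test_perfect_prediction_all_ones(self):
        y = np.array([0, 1, 1, 0, 1])
        _, report = confusion_metrics(y, y)
        assert (report.recall, report.precision, report.f1, report.accuracy) == (1, 1, 1, 1)

    def test_all_negative_predictions_flag_precision(self):
        y_true = np.array([1, 1, 0, 0])
        y_pred = np.zeros(4, dtype=int)
        with pytest.warns(RuntimeWarning):
            _, report = confusion_metrics(y_true, y_pred)
        assert report.recall == 0.0
        assert report.precision == 0.0
        assert "precision" in report.undefined

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            confusion_metrics([0, 2], [0, 1])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
    def test_accuracy_decomposes_by_class(self, tp, tn, fp, fn):
        # accuracy == (recall*P + specificity*N) / (P + N)
        if tp + fn == 0 or tn + fp == 0 or tp + tn + fp + fn == 0:
            return
        y_true = np.r_[np.ones(tp + fn, dtype=int), np.zeros(tn + fp, dtype=int)]
        y_pred = np.r_[np.ones(tp, dtype=int), np.zeros(fn, dtype=int),
                       np.ones(fp, dtype=int), np.zeros(tn, dtype=int)]
        y_pred = np.r_[y_pred[: tp + fn], y_pred[tp + fn:]]
        _, rep = confusion_metrics(y_true, y_pred)
        P, N = tp + fn, tn + fp
        specificity = tn / N
        assert rep.accuracy == pytest.approx((rep.recall * P + specificity * N) / (P + N))


class TestRocAuc:
    def test_perfect_ranking_gives_unit_area(self):
        _, auc = roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert auc == 1.0

    def test_constant_scores_give_half(self):
        _, auc = roc_auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5])
        assert auc == pytest.approx(0.5)

    def test_four_sample_worked_example(self):
        # 3 of 4 positive/negative pairs concordant -> AUC 0.75
        points, auc = roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.2])
        assert auc == pytest.approx(0.75)
        assert auc == pytest.approx(auc_concordance([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.2]))

    def test_curve_is_monotone_staircase(self, rng):
        y = (rng.random(30) > 0.5).astype(int)
        y[:2] = [0, 1]
        scores = rng.standard_normal(30)
        points, _ = roc_auc(y, scores)
        fpr = [p[0] for p in points]
        tpr = [p[1] for p in points]
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)
        assert all(b >= a for a, b in zip(fpr, fpr[1:]))
        assert all(b >= a for a, b in zip(tpr, tpr[1:]))

    @pytest.mark.parametrize("seed", range(5))
    def test_trapezoid_equals_concordance_with_ties(self, seed):
        gen = np.random.default_rng(seed)
        y = (gen.random(40) > 0.4).astype(int)
        y[:2] = [0, 1]
        scores = np.round(gen.standard_normal(40), 1)  # induce ties
        _, auc = roc_auc(y, scores)
        assert auc == pytest.approx(auc_concordance(y, scores), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        y = (rng.random(50) > 0.5).astype(int)
        y[:2] = [0, 1]
        scores = rng.standard_normal(50)
        _, auc = roc_auc(y, scores)
        assert auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=4, max_size=20))
    def test_negating_scores_flips_auc(self, raw):
        n = len(raw)
        y = np.array([i % 2 for i in range(n)])
        scores = np.asarray(raw)
        _, auc = roc_auc(y, scores)
        _, auc_neg = roc_auc(y, -scores)
        assert auc_neg == pytest.approx(1.0 - auc, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_evaluate_predictions_combines_reports(self):
        y = np.array([1, 0, 1, 0, 1, 0])
        pred = np.array([1, 0, 0, 0, 1, 1])
        scores = np.array([0.9, 0.1, 0.3, 0.2, 0.8, 0.6])
        counts, rep = evaluate_predictions(y, pred, scores)
        assert counts.total == 6
        assert rep.auc is not None and rep.roc_points is not None
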