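"""Downstream grading harness: KNN and RBF-SVM classifiers with ROC/AUC metrics.

Selected features feed two standard classifiers — a K-nearest-neighbor
vote (K = 7, Euclidean distance) and a soft-margin SVM with an RBF
kernel whose cost and kernel width are chosen by 10-fold stratified
cross-validation on a coarse power-of-two grid. Performance is
summarized by recall, precision, F1, accuracy and the area under the
ROC curve built from the threshold sweep of the classifier scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "knn_predict",
    "svm_train_predict",
    "confusion_metrics",
    "roc_auc",
    "evaluate_predictions",
]

# classic coarse libsvm grid: powers of four
DEFAULT_C_GRID = tuple(2.0 ** e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** e for e in range(-15, 4, 2))


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """Threshold metrics plus (optionally) the ROC curve and its area.

    Ratios with a zero denominator are reported as 0.0 and listed in
    ``undefined`` so the report stays machine-readable.
    """

    recall: float
    precision: float
    f1: float
    accuracy: float
    auc: float | None = None
    roc_points: tuple | None = None
    undefined: tuple[str, ...] = ()


def knn_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    K: int = 7,
) -> tuple[np.ndarray, np.ndarray]:
    """Majority vote of the K nearest training points (Euclidean distance).

    K must be odd (an even K can tie a binary vote) and no larger than
    the training set. Distance ties are broken toward the lower training
    index, so predictions are deterministic. Returns ``(predictions,
    scores)`` where the score is the fraction of positive neighbors —
    a ranking score usable for ROC analysis.
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y, dtype=int)
    test_X = np.asarray(test_X, dtype=float)
    if K % 2 == 0:
        raise ValueError("K must be odd to preclude vote ties in binary grading")
    if not 1 <= K <= train_X.shape[0]:
        raise ValueError(f"K must be in [1, {train_X.shape[0]}]")
    dist = cdist(test_X, train_X, metric="euclidean")
    # stable argsort: equal distances resolve to the lower training index
    nearest = np.argsort(dist, axis=1, kind="stable")[:, :K]
    scores = train_y[nearest].mean(axis=1)
    preds = (scores > 0.5).astype(int)
    return preds, scores


def svm_train_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    C_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    folds: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """RBF-kernel SVM with stratified-CV hyperparameter search.

    Cost C and kernel width gamma are chosen by ``folds``-fold stratified
    cross-validation (capped at the minority-class count) maximizing
    accuracy; the model is refit on all training data. Returns
    ``(predictions, decision_values, best_params)``; the signed decision
    values serve as ROC scores.
    """
    train_y = np.asarray(train_y, dtype=int)
    counts = np.bincount(train_y, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes must be present in the SVM training data")
    n_splits = int(min(folds, counts.min()))
    if n_splits < 2:
        raise ValueError("minority class too small for cross-validated hyperparameter search")
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    search = GridSearchCV(
        SVC(kernel="rbf"),
        {"C": list(C_grid), "gamma": list(gamma_grid)},
        scoring="accuracy",
        cv=cv,
        n_jobs=None,
    )
    search.fit(np.asarray(train_X, dtype=float), train_y)
    best = search.best_estimator_
    test_X = np.asarray(test_X, dtype=float)
    return best.predict(test_X), best.decision_function(test_X), dict(search.best_params_)


def confusion_metrics(y_true, y_pred) -> tuple[ConfusionCounts, MetricsReport]:
    """Confusion counts and the standard threshold metrics.

    recall = TP/(TP+FN), precision = TP/(TP+FP),
    F1 = 2 PR/(P+R), accuracy = (TP+TN)/total; a zero denominator
    yields 0.0 with the metric flagged in ``undefined``.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary 0/1")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    counts = ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)

    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            warnings.warn(f"{name} undefined (zero denominator); reported as 0", RuntimeWarning)
            return 0.0
        return num / den

    recall = ratio(tp, tp + fn, "recall")
    precision = ratio(tp, tp + fp, "precision")
    f1 = ratio(2 * precision * recall, precision + recall, "f1")
    accuracy = ratio(tp + tn, counts.total, "accuracy")
    return counts, MetricsReport(
        recall=recall, precision=precision, f1=f1, accuracy=accuracy, undefined=tuple(undefined)
    )


def roc_auc(y_true, scores) -> tuple[tuple, float]:
    """ROC curve by descending-threshold sweep and its trapezoidal area.

    Thresholds run over the unique scores from high to low; at each, a
    sample is called positive when its score >= threshold, giving a
    staircase of (FPR, TPR) points from (0,0) to (1,1). The trapezoidal
    area equals the Mann-Whitney concordance probability with ties
    counted one half.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must have equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = (y_true[order] == 1).astype(float)
    tp_cum = np.cumsum(sorted_pos)
    fp_cum = np.cumsum(1.0 - sorted_pos)
    # keep only the last point of each tied-score block
    last_of_block = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tp_cum[last_of_block] / n_pos]
    fpr = np.r_[0.0, fp_cum[last_of_block] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    points = tuple(zip(fpr.tolist(), tpr.tolist()))
    return points, auc


def evaluate_predictions(y_true, y_pred, scores) -> tuple[ConfusionCounts, MetricsReport]:
    """Full report: confusion metrics plus ROC/AUC from the scores."""
    counts, base = confusion_metrics(y_true, y_pred)
    points, auc = roc_auc(y_true, scores)
    return counts, MetricsReport(
        recall=base.recall,
        precision=base.precision,
        f1=base.f1,
        accuracy=base.accuracy,
        auc=auc,
        roc_points=points,
        undefined=base.undefined,
    )
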