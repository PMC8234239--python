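"""Leave-one-out logistic-regression classification and the metric suite.

Three-class (BQ/TA/HC) and one-vs-one binary tasks over latent feature
vectors.  Each LOOCV fold standardizes features with training-fold
statistics only, refits an L2-regularized multinomial logistic regression,
and predicts the held-out unit (a map, or a whole subject when
``grouping='subject'``).  ROC/AUC pools the n held-out class probabilities
into one curve, the only well-defined construction under LOOCV.

Metrics: confusion matrix, overall accuracy, per-class correct
classification rate (CCR = per-class recall), Cohen's kappa, and per-pair
precision/recall/F1/AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.preprocessing import StandardScaler

# L2 penalty (sklearn's default) at unit inverse-strength; deterministic lbfgs
LR_SETTINGS = dict(C=1.0, solver="lbfgs", max_iter=5000)


@dataclass
class CohortFeatures:
    """Feature matrix (maps x features) with labels and subject ids."""

    matrix: np.ndarray
    labels: list[str]
    subject_ids: list[str] | None = None
    feature_kind: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.labels):
            raise ValueError(f"matrix rows {self.matrix.shape} != labels {len(self.labels)}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite values")
        if self.subject_ids is None:
            self.subject_ids = [f"map{i:03d}" for i in range(len(self.labels))]
        if len(self.subject_ids) != len(self.labels):
            raise ValueError("subject_ids length must match labels")


def loocv_folds(n: int, subject_ids: list[str] | None, grouping: str = "map"
                ) -> list[tuple[np.ndarray, np.ndarray]]:
    """(train_idx, test_idx) per fold: one map, or one subject, held out."""
    if grouping == "map":
        units = [np.array([i]) for i in range(n)]
    elif grouping == "subject":
        order: dict[str, list[int]] = {}
        for i, sid in enumerate(subject_ids):
            order.setdefault(sid, []).append(i)
        units = [np.array(v) for v in order.values()]
    else:
        raise ValueError(f"grouping must be 'map' or 'subject', got {grouping!r}")
    all_idx = np.arange(n)
    return [(np.setdiff1d(all_idx, test), test) for test in units]


def fit_predict_proba(x_train: np.ndarray, y_train: np.ndarray, x_test: np.ndarray,
                      class_order: list[str], seed: int = 0
                      ) -> np.ndarray:
    """Standardize on training stats, fit LR, return (n_test, n_classes) probabilities."""
    scaler = StandardScaler().fit(x_train)
    clf = LogisticRegression(random_state=seed, **LR_SETTINGS)
    clf.fit(scaler.transform(x_train), y_train)
    proba = clf.predict_proba(scaler.transform(x_test))
    # re-order columns to the requested class order
    cols = [list(clf.classes_).index(c) for c in class_order]
    return proba[:, cols]


def _argmax_label(proba_row: np.ndarray, class_order: list[str]) -> str:
    """Highest probability wins; exact ties break to the lexicographically first label."""
    best = proba_row.max()
    tied = [c for c, p in zip(class_order, proba_row) if p == best]
    return min(tied)


def loocv_predict(features: CohortFeatures, task: str | tuple[str, str] = "multiclass",
                  seed: int = 0, grouping: str = "map"
                  ) -> tuple[list[str], list[str], np.ndarray, list[str]]:
    """LOOCV predictions and held-out class probabilities.

    ``task`` is ``'multiclass'`` or a pair of class labels (one-vs-one;
    other classes are dropped).  Returns (y_true, y_pred, scores,
    class_order) with scores[i, j] the held-out probability of class j.
    """
    matrix, labels = features.matrix, list(features.labels)
    subject_ids = list(features.subject_ids)
    if task != "multiclass":
        c1, c2 = task
        keep = [i for i, lab in enumerate(labels) if lab in (c1, c2)]
        matrix = matrix[keep]
        labels = [labels[i] for i in keep]
        subject_ids = [subject_ids[i] for i in keep]
    class_order = sorted(set(labels))
    counts = {c: labels.count(c) for c in class_order}
    if min(counts.values()) < 3:
        raise ValueError(f"need >= 3 maps per retained class, got {counts}")
    y = np.asarray(labels)
    y_pred: list[str] = [""] * len(y)
    scores = np.zeros((len(y), len(class_order)))
    for fold_idx, (train, test) in enumerate(
            loocv_folds(len(y), subject_ids, grouping)):
        if set(class_order) - set(y[train]):
            missing = sorted(set(class_order) - set(y[train]))
            raise ValueError(f"fold {fold_idx}: class(es) {missing} absent from training data")
        proba = fit_predict_proba(matrix[train], y[train], matrix[test],
                                  class_order, seed=seed)
        for row, idx in zip(proba, test):
            scores[idx] = row
            y_pred[idx] = _argmax_label(row, class_order)
    return list(y), y_pred, scores, class_order


def confusion_matrix(y_true, y_pred, class_order: list[str]) -> np.ndarray:
    """Counts with entry (i, j) = true class i predicted as class j."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    index = {c: i for i, c in enumerate(class_order)}
    out = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label {t if t not in index else p!r} outside class order "
                             f"{class_order}")
        out[index[t], index[p]] += 1
    return out


def multiclass_report(confusion: np.ndarray) -> dict:
    """Accuracy, per-class CCR and Cohen's kappa from a confusion matrix.

    accuracy = trace/total; CCR_c = diagonal_c / row-sum_c (None when the
    class has no true samples); kappa = (p_o - p_e)/(1 - p_e) with
    p_e = sum_c rowsum_c * colsum_c / total^2.
    """
    confusion = np.asarray(confusion, dtype=float)
    total = confusion.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    row = confusion.sum(axis=1)
    col = confusion.sum(axis=0)
    diag = np.diag(confusion)
    p_o = diag.sum() / total
    p_e = float((row * col).sum()) / total**2
    kappa = 0.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    ccr = [float(d / r) if r > 0 else None for d, r in zip(diag, row)]
    return {"accuracy": float(p_o), "ccr_per_class": ccr, "kappa": float(kappa)}


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def auc_trapezoidal(y_true, scores, positive_class) -> float:
    """Area under the ROC built from pooled scores, by the trapezoidal rule."""
    y = np.asarray([1 if t == positive_class else 0 for t in y_true])
    if y.min() == y.max():
        raise ValueError("AUC needs both classes present")
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float))
    return float(np.trapezoid(tpr, fpr))


def binary_report(y_true, y_pred, scores, positive_class) -> dict:
    """Precision, recall, F1 and AUC for one one-vs-one pair.

    ``scores`` are the pooled held-out probabilities of the positive class.
    When no sample is predicted positive, precision and F1 are None.
    """
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == positive_class and p == positive_class)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t != positive_class and p == positive_class)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == positive_class and p != positive_class)
    recall = tp / (tp + fn) if tp + fn > 0 else None
    if tp + fp == 0:
        precision = f1 = None
    else:
        precision = tp / (tp + fp)
        f1 = (f1_from_precision_recall(precision, recall)
              if recall is not None else None)
    accuracy = float(np.mean([t == p for t, p in zip(y_true, y_pred)]))
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1,
            "auc": auc_trapezoidal(y_true, scores, positive_class)}


@dataclass
class ClassificationReport:
    """Multiclass + one-vs-one LOOCV results for one feature kind."""

    feature_kind: str
    class_order: list[str]
    confusion: np.ndarray
    multiclass: dict
    pairs: dict[str, dict]
    fold_predictions: pd.DataFrame
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "feature_kind": self.feature_kind,
            "class_order": self.class_order,
            "confusion": self.confusion.tolist(),
            "multiclass": self.multiclass,
            "pairs": self.pairs,
            "settings": self.settings,
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        self.fold_predictions.to_csv(path.with_suffix(".predictions.csv"), index=False)


def evaluate_features(features: CohortFeatures, seed: int = 0,
                      grouping: str = "map") -> ClassificationReport:
    """Full report: multiclass LOOCV plus every one-vs-one pair."""
    y_true, y_pred, scores, class_order = loocv_predict(
        features, "multiclass", seed=seed, grouping=grouping)
    conf = confusion_matrix(y_true, y_pred, class_order)
    pairs: dict[str, dict] = {}
    for i, c1 in enumerate(class_order):
        for c2 in class_order[i + 1:]:
            yt, yp, sc, order = loocv_predict(features, (c1, c2), seed=seed,
                                              grouping=grouping)
            pos = c2  # positive class: second label of the sorted pair
            pairs[f"{c1}_vs_{c2}"] = binary_report(yt, yp, sc[:, order.index(pos)], pos)
            pairs[f"{c1}_vs_{c2}"]["positive_class"] = pos
    fold_df = pd.DataFrame({
        "subject_id": features.subject_ids, "true": y_true, "predicted": y_pred,
        **{f"p_{c}": scores[:, j] for j, c in enumerate(class_order)}})
    return ClassificationReport(
        feature_kind=features.feature_kind, class_order=class_order,
        confusion=conf, multiclass=multiclass_report(conf), pairs=pairs,
        fold_predictions=fold_df,
        settings={"grouping": grouping, "seed": seed, "lr": LR_SETTINGS,
                  "standardization": "per-training-fold mean/SD"})
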