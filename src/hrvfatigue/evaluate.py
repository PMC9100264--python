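"""Fatigue classification and subject-grouped cross-validated evaluation.

Four classifier families (decision tree, RBF support-vector machine,
k-nearest neighbors, gradient-boosted trees) are evaluated with 10-fold
cross-validation grouped by subject: all segments of a subject live in the
same fold, so no subject's data is split between training and testing.
Metrics are one-vs-rest precision/recall/F1 per class, macro-averaged, and
overall accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.impute import SimpleImputer
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

MODEL_KINDS = ("dt", "svm", "knn", "gbt")

#: Documented default hyperparameters per model family. The gradient
#: boosting entry is a histogram-based GBDT (the LightGBM algorithm family).
DEFAULT_MODEL_PARAMS = {
    "dt": dict(criterion="gini", max_depth=None),
    "svm": dict(kernel="rbf", C=1.0),
    "knn": dict(n_neighbors=5, metric="euclidean"),
    "gbt": dict(max_iter=100, learning_rate=0.1),
}
#: Families whose distance/margin geometry needs standardized inputs.
_SCALED = {"svm", "knn"}


@dataclass
class Metrics:
    """Macro-averaged classification metrics plus per-class breakdown."""

    acc: float
    precision: float
    recall: float
    f1: float
    per_class: dict  # class -> dict(precision, recall, f1, support)


@dataclass
class CVResult:
    per_fold: list
    mean: dict
    std: dict
    pooled_confusion: pd.DataFrame  # rows = true class, cols = predicted
    model_kind: str
    fold_assignment: dict  # subject -> fold


class FatigueClassifier(ClassifierMixin, BaseEstimator):
    """One of the four fatigue classifier families behind a uniform
    sklearn interface.

    Median imputation (for NaN feature values) and, for the SVM/KNN
    families, standardization are fitted on the training data only and
    applied at prediction time.

    Parameters
    ----------
    model : {"dt", "svm", "knn", "gbt"}
    model_params : dict or None
        Overrides merged into the family's documented defaults.
    random_state : int or None
    """

    def __init__(self, model: str = "gbt", model_params: dict | None = None,
                 random_state: int | None = None):
        self.model = model
        self.model_params = model_params
        self.random_state = random_state

    def _build(self) -> Pipeline:
        if self.model not in MODEL_KINDS:
            raise ValueError(
                f"unknown model kind {self.model!r}; choose from {MODEL_KINDS}")
        params = dict(DEFAULT_MODEL_PARAMS[self.model],
                      **(self.model_params or {}))
        if self.model == "dt":
            est = DecisionTreeClassifier(random_state=self.random_state, **params)
        elif self.model == "svm":
            est = SVC(random_state=self.random_state, **params)
        elif self.model == "knn":
            est = KNeighborsClassifier(**params)
        else:
            est = HistGradientBoostingClassifier(
                random_state=self.random_state, **params)
        steps = [("impute", SimpleImputer(strategy="median"))]
        if self.model in _SCALED:
            steps.append(("scale", StandardScaler()))
        steps.append(("clf", est))
        return Pipeline(steps)

    def fit(self, X, y):
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 3:
            logger.warning("training data has %d classes (expected 3); "
                           "fitting anyway", classes.size)
        self.pipeline_ = self._build()
        self.pipeline_.fit(np.asarray(X, dtype=float), y)
        self.classes_ = self.pipeline_.named_steps["clf"].classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict(np.asarray(X, dtype=float))


def fit_classifier(X, y, model_kind: str = "gbt",
                   seed: int | None = None,
                   model_params: dict | None = None) -> FatigueClassifier:
    clf = FatigueClassifier(model=model_kind, model_params=model_params,
                            random_state=seed)
    return clf.fit(X, y)


def grouped_kfold(subjects, k: int = 10,
                  seed: int | None = None) -> dict:
    """Randomly partition distinct subjects into k folds of near-equal
    size (sizes differ by at most 1). Returns subject -> fold index."""
    uniq = sorted(set(subjects))
    if len(uniq) < k:
        raise ValueError(
            f"need at least {k} distinct subjects for {k}-fold CV, "
            f"got {len(uniq)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    return {uniq[idx]: i % k for i, idx in enumerate(order)}


def compute_metrics(y_true, y_pred, labels=None) -> Metrics:
    """Accuracy plus macro-averaged one-vs-rest precision/recall/F1.

    Per class: precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2PR/(P+R); a zero denominator yields 0 with a warning. Accuracy
    is overall correct/total. Macro values are unweighted class means.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))

    per_class = {}
    precs, recs, f1s = [], [], []
    for c in labels:
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        support = int(np.sum(y_true == c))
        if tp + fp == 0:
            logger.warning("class %r has no predicted positives; "
                           "precision set to 0", c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[c] = {"precision": prec, "recall": rec, "f1": f1,
                        "support": support}
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)
    return Metrics(
        acc=float(np.mean(y_true == y_pred)),
        precision=float(np.mean(precs)),
        recall=float(np.mean(recs)),
        f1=float(np.mean(f1s)),
        per_class=per_class)


def cross_validate(X, y, groups, model_kind: str = "gbt", k: int = 10,
                   seed: int | None = None,
                   model_params: dict | None = None,
                   labels=None) -> CVResult:
    """Subject-grouped k-fold cross-validation of one model family.

    Each fold trains on the other folds' subjects and tests on its own;
    per-fold metrics are averaged (mean +/- sd) and confusion counts are
    pooled over folds (rows = true class, columns = predicted class).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.asarray(groups)
    if not (len(X) == len(y) == len(groups)):
        raise ValueError("X, y and groups must have equal length")
    if labels is None:
        labels = sorted(set(y))
    assignment = grouped_kfold(groups, k=k, seed=seed)
    fold_of = np.array([assignment[g] for g in groups])

    per_fold = []
    confusion = pd.DataFrame(0, index=list(labels), columns=list(labels))
    for fold in range(k):
        test = fold_of == fold
        train = ~test
        train_subj = set(groups[train])
        test_subj = set(groups[test])
        assert not train_subj & test_subj, "subject leakage across folds"
        if not np.any(test):
            continue
        clf = fit_classifier(X[train], y[train], model_kind=model_kind,
                             seed=seed, model_params=model_params)
        pred = clf.predict(X[test])
        per_fold.append(compute_metrics(y[test], pred, labels=labels))
        for t, p in zip(y[test], pred):
            confusion.loc[t, p] += 1

    metric_names = ("acc", "precision", "recall", "f1")
    mean = {m: float(np.mean([getattr(f, m) for f in per_fold]))
            for m in metric_names}
    std = {m: float(np.std([getattr(f, m) for f in per_fold], ddof=1))
           for m in metric_names}
    return CVResult(per_fold=per_fold, mean=mean, std=std,
                    pooled_confusion=confusion, model_kind=model_kind,
                    fold_assignment=assignment)
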