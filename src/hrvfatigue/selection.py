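"""Label-permutation null-importance feature selection.

The selector scores each feature by comparing its actual random-forest Gini
importance I{f} against a null distribution D{f} obtained by refitting the
forest T times on label-permuted copies of the data (the features are never
touched — only the labels are shuffled). The score is the percentage of
null draws strictly below the actual importance:

    score(f) = count(D{f} < I{f}) / T * 100

Features whose score does not exceed the threshold r1 are dropped as
unimportant (Phi1). Among the survivors, for every pair with absolute
Pearson correlation above r2 the member with the smaller actual importance
is dropped as redundant (Phi2). The remainder is the selected set Phi'.

Note on r1: with the default r1 = 0, "score lower than r1" is read as
score <= r1, so exactly the features whose actual importance never beats a
single null draw are removed; a strict < would make r1 = 0 a no-op.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

DEFAULT_RF_PARAMS = dict(n_estimators=100, max_features="sqrt", max_depth=None)


@dataclass
class ImportanceReport:
    """Actual importances, null distributions and permutation scores."""

    feature_names: list[str]
    actual: dict[str, float]
    null: dict[str, np.ndarray]  # each of length n_permutations
    scores: dict[str, float]  # percent in [0, 100]
    n_permutations: int
    seed: int | None


@dataclass
class SelectionResult:
    """Outcome of the two-stage selection: Phi1 (unimportant), Phi2
    (redundant) and the selected set Phi', which partition the input
    feature list."""

    selected: list[str]
    phi1_dropped: list[str]
    phi2_dropped: list[str]
    r1: float
    r2: float
    correlation: pd.DataFrame  # over post-Phi1 features
    report: ImportanceReport

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "phi1_dropped": self.phi1_dropped,
            "phi2_dropped": self.phi2_dropped,
            "r1": self.r1,
            "r2": self.r2,
            "scores": self.report.scores,
            "actual_importance": self.report.actual,
            "null_importance_mean": {
                f: float(np.mean(d)) for f, d in self.report.null.items()},
            "n_permutations": self.report.n_permutations,
            "seed": self.report.seed,
        }


def _as_frame(X, feature_names=None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X)
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=list(feature_names))


def _forest_importances(X: np.ndarray, y: np.ndarray, rf_params: dict,
                        seed: int) -> np.ndarray:
    """Unnormalized Gini importance: the accumulated impurity decrease over
    all split nodes of all trees (sklearn's per-tree sums without the
    global normalization, so values are comparable across refits)."""
    rf = RandomForestClassifier(random_state=seed, **rf_params)
    rf.fit(X, y)
    return np.sum(
        [t.tree_.compute_feature_importances(normalize=False)
         for t in rf.estimators_], axis=0)


def gini_importance(X, y, rf_params: dict | None = None,
                    seed: int | None = None) -> dict[str, float]:
    """Actual Gini importance I{f} per feature from one forest fit."""
    Xf = _as_frame(X)
    y = np.asarray(y)
    if Xf.shape[0] < 10:
        raise ValueError(f"need >= 10 instances, got {Xf.shape[0]}")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes to fit the forest")
    params = dict(DEFAULT_RF_PARAMS, **(rf_params or {}))
    imp = _forest_importances(Xf.to_numpy(), y, params, seed or 0)
    return dict(zip(Xf.columns, map(float, imp)))


def null_importance_distribution(X, y, n_permutations: int = 100,
                                 rf_params: dict | None = None,
                                 seed: int | None = None) -> dict[str, np.ndarray]:
    """Null importances D{f}: refit the same forest on T label
    permutations; X is never altered."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    Xf = _as_frame(X)
    y = np.asarray(y)
    params = dict(DEFAULT_RF_PARAMS, **(rf_params or {}))
    rng = np.random.default_rng(seed)
    Xa = Xf.to_numpy()
    draws = np.empty((n_permutations, Xf.shape[1]))
    for i in range(n_permutations):
        y_perm = rng.permutation(y)
        fit_seed = int(rng.integers(0, 2**31 - 1))
        draws[i] = _forest_importances(Xa, y_perm, params, fit_seed)
    return {f: draws[:, j].copy() for j, f in enumerate(Xf.columns)}


def feature_score(actual: float, null: np.ndarray) -> float:
    """Percentage of null draws strictly below the actual importance;
    ties count against the feature."""
    null = np.asarray(null)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    return float(np.count_nonzero(null < actual) / null.size * 100.0)


def drop_unimportant(scores: dict[str, float], r1: float = 0.0) -> list[str]:
    """Phi1: features with score <= r1, in original feature order."""
    return [f for f, s in scores.items() if s <= r1]


def correlation_matrix(X) -> pd.DataFrame:
    """Pearson correlation matrix of the feature columns. Correlations
    involving a zero-variance column are undefined and reported as 0 so
    they can never trigger redundancy pruning."""
    Xf = _as_frame(X)
    if Xf.shape[0] < 3:
        raise ValueError("need >= 3 instances for a correlation matrix")
    corr = Xf.corr(method="pearson")
    corr = corr.fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def remove_redundant(corr: pd.DataFrame, importance: dict[str, float],
                     r2: float = 0.9) -> list[str]:
    """Phi2: the less important member of each highly correlated pair.

    Pairs with |r| > r2 are processed in descending |r|; a pair both of
    whose members still survive contributes its lower-importance member
    (ties: the one appearing later in the feature order). A pair is
    skipped when either member was already removed, so nothing is dropped
    for correlating with an already-removed feature.
    """
    feats = list(corr.columns)
    order = {f: i for i, f in enumerate(feats)}
    pairs = []
    for i, a in enumerate(feats):
        for b in feats[i + 1:]:
            r = abs(float(corr.loc[a, b]))
            if r > r2:
                pairs.append((r, a, b))
    pairs.sort(key=lambda p: (-p[0], order[p[1]], order[p[2]]))
    removed: list[str] = []
    for _, a, b in pairs:
        if a in removed or b in removed:
            continue
        ia, ib = importance[a], importance[b]
        if ia < ib or (ia == ib and order[a] > order[b]):
            removed.append(a)
        else:
            removed.append(b)
    return sorted(removed, key=order.__getitem__)


class NullImportanceSelector(SelectorMixin, BaseEstimator):
    """Feature selector combining permutation-null importance scoring with
    redundancy pruning.

    Parameters
    ----------
    r1 : float, default=0.0
        Score threshold (percent); features with score <= r1 are dropped
        as unimportant.
    r2 : float, default=0.9
        Absolute Pearson correlation above which a feature pair is
        considered redundant.
    n_permutations : int, default=100
        Number of label permutations T for the null distribution.
    rf_params : dict or None
        Overrides for the random-forest configuration (100 trees, sqrt
        features per split, unlimited depth). The same configuration is
        used for the actual and every null fit.
    random_state : int or None
        Seed for the permutation stream and forest fits; fixing it makes
        the whole selection deterministic.

    Attributes
    ----------
    feature_names_in_ : list of str
    importances_ : dict feature -> actual Gini importance
    null_importances_ : dict feature -> array of T null importances
    scores_ : dict feature -> percent score in [0, 100]
    phi1_dropped_ : list of unimportant features
    phi2_dropped_ : list of redundant features
    selected_features_ : the surviving feature list Phi'
    correlation_ : DataFrame, Pearson matrix over post-Phi1 features
    result_ : SelectionResult
    """

    def __init__(self, r1: float = 0.0, r2: float = 0.9,
                 n_permutations: int = 100, rf_params: dict | None = None,
                 random_state: int | None = None):
        self.r1 = r1
        self.r2 = r2
        self.n_permutations = n_permutations
        self.rf_params = rf_params
        self.random_state = random_state

    def fit(self, X, y):
        Xf = _as_frame(X)
        y = np.asarray(y)
        feats = list(Xf.columns)
        if len(set(feats)) != len(feats):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(Xf.to_numpy(dtype=float))):
            raise ValueError("X contains non-finite values; impute first")

        rng = np.random.default_rng(self.random_state)
        actual_seed = int(rng.integers(0, 2**31 - 1))
        null_seed = int(rng.integers(0, 2**31 - 1))
        self.importances_ = gini_importance(
            Xf, y, rf_params=self.rf_params, seed=actual_seed)
        self.null_importances_ = null_importance_distribution(
            Xf, y, n_permutations=self.n_permutations,
            rf_params=self.rf_params, seed=null_seed)
        self.scores_ = {
            f: feature_score(self.importances_[f], self.null_importances_[f])
            for f in feats}
        self.phi1_dropped_ = drop_unimportant(self.scores_, self.r1)
        survivors = [f for f in feats if f not in self.phi1_dropped_]
        if survivors:
            self.correlation_ = correlation_matrix(Xf[survivors])
            self.phi2_dropped_ = remove_redundant(
                self.correlation_, self.importances_, self.r2)
        else:
            self.correlation_ = pd.DataFrame()
            self.phi2_dropped_ = []
        self.selected_features_ = [
            f for f in survivors if f not in self.phi2_dropped_]

        self.feature_names_in_ = np.asarray(feats, dtype=object)
        self.n_features_in_ = len(feats)
        self.support_ = np.array(
            [f in self.selected_features_ for f in feats])
        report = ImportanceReport(
            feature_names=feats, actual=self.importances_,
            null=self.null_importances_, scores=self.scores_,
            n_permutations=self.n_permutations, seed=self.random_state)
        self.result_ = SelectionResult(
            selected=self.selected_features_,
            phi1_dropped=self.phi1_dropped_,
            phi2_dropped=self.phi2_dropped_,
            r1=self.r1, r2=self.r2, correlation=self.correlation_,
            report=report)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def _more_tags(self):  # pragma: no cover
        return {"allow_nan": False, "requires_y": True}


def select_features(X, y, r1: float = 0.0, r2: float = 0.9,
                    n_permutations: int = 100,
                    rf_params: dict | None = None,
                    seed: int | None = None) -> SelectionResult:
    """Functional wrapper around :class:`NullImportanceSelector`."""
    sel = NullImportanceSelector(
        r1=r1, r2=r2, n_permutations=n_permutations,
        rf_params=rf_params, random_state=seed)
    sel.fit(X, y)
    return sel.result_
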