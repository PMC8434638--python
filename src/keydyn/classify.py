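"""Cross-validated classification of opinion valence and PAD levels.

The modeling protocol: stratified k-fold (default 10) cross-validation;
inside every training fold the pipeline imputes missing features with
training-fold column means, optionally standardizes, screens features by
variance and pairwise correlation, and tunes the classifier by an inner
grid-search CV.  Held-out predictions from all folds are pooled into a
single confusion matrix, from which per-class precision/recall/F1 and the
macro (valence task) or support-weighted (pleasure/arousal tasks) averages
are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .dataset import Dataset, impute_column_means, reduce_features
from .types import OpinionKind, Valence

#: Default hyper-parameter grids per model family.
DEFAULT_GRIDS: dict[str, dict[str, list[Any]]] = {
    "svm": {"C": [0.1, 1.0, 10.0, 100.0], "gamma": ["scale", 0.01, 0.1, 1.0]},
    "random_forest": {"n_estimators": [100], "max_depth": [None, 5, 10]},
    "naive_bayes": {},
    "knn": {"n_neighbors": [3, 5, 7]},
}


def _make_model(model: str, seed: int):
    if model == "svm":
        return SVC(kernel="rbf", random_state=seed)
    if model == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if model == "naive_bayes":
        return GaussianNB()
    if model == "knn":
        return KNeighborsClassifier()
    raise ValueError(f"unknown model {model!r}")


@dataclass
class ClassificationReport:
    """Pooled cross-validation result.

    ``confusion`` rows are true classes, columns predicted classes, summed
    over all test folds; metric Series are indexed by class label.
    """

    classes: list[str]
    confusion: np.ndarray
    precision: pd.Series
    recall: pd.Series
    f1: pd.Series
    macro_f1: float
    weighted_f1: float
    macro_precision: float
    macro_recall: float
    weighted_precision: float
    weighted_recall: float
    n: int
    model: str
    seed: int
    best_params: list[dict[str, Any]] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
            "precision": self.precision.to_dict(),
            "recall": self.recall.to_dict(),
            "f1": self.f1.to_dict(),
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "n": self.n,
            "model": self.model,
            "seed": self.seed,
            "best_params": self.best_params,
        }


def assign_valence_labels(dataset: Dataset) -> np.ndarray:
    """POSITIVE for best-teacher/best-subject segments, NEGATIVE for worst."""
    kinds = dataset.meta["opinion_kind"]
    valid = {k.value for k in OpinionKind}
    unknown = sorted(set(kinds) - valid)
    if unknown:
        raise ValueError(f"unknown opinion kind(s): {unknown}")
    positive = kinds.isin([OpinionKind.BEST_TEACHER.value, OpinionKind.BEST_SUBJECT.value])
    return np.where(positive, Valence.POSITIVE.value, Valence.NEGATIVE.value)


def cross_validated_classify(
    X: pd.DataFrame,
    labels,
    model: str = "svm",
    grid: dict[str, list[Any]] | None = None,
    k_folds: int = 10,
    seed: int = 0,
    scale: bool = False,
    reduce: bool = True,
    var_threshold: float = 1e-10,
    corr_threshold: float = 0.95,
    nested: bool = True,
    inner_folds: int = 3,
) -> ClassificationReport:
    """Stratified k-fold CV with leakage-safe per-fold preprocessing.

    Imputation means, standardization moments, the feature screen and the
    grid search are all fit on the training fold only.  With ``nested=False``
    the grid is tuned once on the full dataset first (replication mode, not
    leakage-safe).
    """
    y = np.asarray(labels)
    X = X.reset_index(drop=True)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("labels contain a single class: nothing to classify")
    if counts.min() < k_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples, fewer than k_folds={k_folds}"
        )
    grid = DEFAULT_GRIDS[model] if grid is None else grid

    fixed_params: dict[str, Any] | None = None
    if not nested:
        Xi, _ = impute_column_means(X)
        cols = reduce_features(Xi, var_threshold, corr_threshold) if reduce else list(Xi.columns)
        gs = GridSearchCV(_make_model(model, seed), grid, cv=inner_folds, scoring="f1_macro")
        gs.fit(_maybe_scale(Xi[cols], scale)[0], y)
        fixed_params = gs.best_params_

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    y_true_all, y_pred_all, best_params = [], [], []
    for train_idx, test_idx in skf.split(X, y):
        X_train, X_test = X.iloc[train_idx], X.iloc[test_idx]
        y_train = y[train_idx]

        X_train, means = impute_column_means(X_train)
        X_test, _ = impute_column_means(X_test, means)
        cols = (
            reduce_features(X_train, var_threshold, corr_threshold)
            if reduce
            else list(X_train.columns)
        )
        X_train, X_test = X_train[cols], X_test[cols]
        X_train, moments = _maybe_scale(X_train, scale)
        X_test, _ = _maybe_scale(X_test, scale, moments)

        if fixed_params is not None:
            clf = _make_model(model, seed).set_params(**fixed_params)
            clf.fit(X_train, y_train)
            best_params.append(dict(fixed_params))
        elif grid:
            gs = GridSearchCV(_make_model(model, seed), grid, cv=inner_folds, scoring="f1_macro")
            gs.fit(X_train, y_train)
            clf = gs.best_estimator_
            best_params.append(gs.best_params_)
        else:
            clf = _make_model(model, seed)
            clf.fit(X_train, y_train)
            best_params.append({})

        y_true_all.extend(y[test_idx])
        y_pred_all.extend(clf.predict(X_test))

    class_list = list(classes)
    cm = confusion_matrix(y_true_all, y_pred_all, labels=class_list)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true_all, y_pred_all, labels=class_list, zero_division=0
    )
    macro = precision_recall_fscore_support(
        y_true_all, y_pred_all, labels=class_list, average="macro", zero_division=0
    )
    weighted = precision_recall_fscore_support(
        y_true_all, y_pred_all, labels=class_list, average="weighted", zero_division=0
    )
    return ClassificationReport(
        classes=[str(c) for c in class_list],
        confusion=cm,
        precision=pd.Series(prec, index=class_list),
        recall=pd.Series(rec, index=class_list),
        f1=pd.Series(f1, index=class_list),
        macro_precision=float(macro[0]),
        macro_recall=float(macro[1]),
        macro_f1=float(macro[2]),
        weighted_precision=float(weighted[0]),
        weighted_recall=float(weighted[1]),
        weighted_f1=float(weighted[2]),
        n=len(y),
        model=model,
        seed=seed,
        best_params=best_params,
    )


def _maybe_scale(X: pd.DataFrame, scale: bool, moments=None):
    if not scale:
        return X, None
    if moments is None:
        mean = X.mean(axis=0)
        std = X.std(axis=0, ddof=0).replace(0.0, 1.0)
        moments = (mean, std)
    mean, std = moments
    return (X - mean) / std, moments
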