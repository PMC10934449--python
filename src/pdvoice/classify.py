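"""Nested cross-validated classification with three model families.

The three families mirror common clinical-speech baselines: a cubic
(polynomial degree 3) SVM with a one-vs-one decision scheme, a 1-nearest-
neighbour classifier with Euclidean distance, and a "wide" single-hidden-
layer neural network with 100 rectified units.  Hyperparameters are
selected by an inner stratified k-fold loop on each outer training
portion; the outer loop estimates generalisation.  The fitted model is
refit on the whole training table with the majority-vote hyperparameter
choice (ties broken toward the smallest value) and evaluated exactly
once on the held-out test table.

Fold bookkeeping (outer/inner index sets) is returned alongside every
report so leakage-freedom is checkable programmatically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from collections import Counter

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .datasets import FeatureTable, feature_subset_columns
from .features import zscore_fit, zscore_apply

FAMILIES = ("cubic_svm", "knn1", "wide_nn")
FEATURE_SUBSETS = ("mfcc", "gtcc", "both")

#: inner-loop hyperparameter grids; knn1 has nothing tunable, so its inner
#: loop degenerates (recorded as hyperparameter None on every fold)
GRIDS: dict[str, list] = {
    "cubic_svm": [0.1, 1.0, 10.0],   # margin-penalty constant C
    "knn1": [None],
    "wide_nn": [1e-4, 1e-2, 1.0],    # ridge (L2) penalty alpha
}


@dataclass(frozen=True)
class ModelSpec:
    family: str

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")

    @property
    def grid(self) -> list:
        return GRIDS[self.family]


@dataclass(frozen=True)
class CVConfig:
    k_outer: int = 5
    k_inner: int = 5
    seed: int = 0
    positive_class: str = "PD"

    def __post_init__(self) -> None:
        if self.k_outer < 2 or self.k_inner < 2:
            raise ValueError("fold counts must be >= 2")


@dataclass
class CVReport:
    family: str
    feature_subset: str
    training_accuracy: float  # mean outer-fold training-portion accuracy
    outer_cv_accuracy: float  # mean outer-fold validation accuracy
    test_accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    f1: float | None = None
    confusion_cv: list | None = None    # aggregated outer-validation 2x2
    confusion_test: list | None = None  # held-out test 2x2
    chosen_params: list = field(default_factory=list)
    final_param: object = None
    seed: int = 0
    fold_bookkeeping: dict | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "fold_bookkeeping"}
        return json.loads(json.dumps(d, default=float))


def make_estimator(family: str, param, seed: int):
    if family == "cubic_svm":
        return SVC(kernel="poly", degree=3, coef0=1.0, C=param,
                   decision_function_shape="ovo")
    if family == "knn1":
        return KNeighborsClassifier(n_neighbors=1, metric="euclidean")
    if family == "wide_nn":
        return MLPClassifier(hidden_layer_sizes=(100,), activation="relu",
                             alpha=param, solver="lbfgs", max_iter=400,
                             random_state=seed)
    raise ValueError(family)


def _fit(est, X, y):
    # the wide network may stop at the lbfgs iteration cap; that cap is a
    # deliberate compute bound, not a failure
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return est


def _confusion(y_true, y_pred, positive: str) -> np.ndarray:
    """2x2 matrix [[TP, FN], [FP, TN]] with ``positive`` the disease class."""
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    return np.array([[tp, fn], [fp, tn]])


def metrics_from_confusion(cm: np.ndarray) -> dict[str, float]:
    (tp, fn), (fp, tn) = cm
    n = tp + fn + fp + tn
    return {
        "accuracy": (tp + tn) / n,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "f1": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan"),
    }


def nested_cv_train(
    train: FeatureTable,
    model: ModelSpec,
    cv: CVConfig,
    feature_subset: str = "both",
):
    """Nested stratified CV on the training table; returns (fitted, report).

    The inner loop grid-searches on each outer-training portion only;
    the outer validation folds are used once each, for performance
    estimation.  The returned model is refit on the full table with the
    majority-vote hyperparameter (ties -> smallest).
    """
    cols = feature_subset_columns(feature_subset)
    X = train.matrix(cols)
    y = train.labels
    if len(set(y)) < 2:
        raise ValueError("training table must contain both classes")
    min_class = min(np.sum(y == c) for c in set(y))
    # every inner fold must still see both classes: the smallest class is
    # split k_outer ways, then its outer-train share k_inner ways
    needed = cv.k_outer * cv.k_inner / (cv.k_outer - 1)
    if min_class < needed:
        raise ValueError(
            f"smallest class has {min_class} rows; nested "
            f"{cv.k_outer}x{cv.k_inner}-fold CV needs at least "
            f"{int(np.ceil(needed))} - enlarge the table or reduce the fold counts"
        )
    outer = StratifiedKFold(cv.k_outer, shuffle=True, random_state=cv.seed)
    chosen, outer_val_acc, outer_train_acc = [], [], []
    cm_cv = np.zeros((2, 2), dtype=int)
    bookkeeping = {"outer": [], "inner": []}
    for fold_i, (tr_idx, val_idx) in enumerate(outer.split(X, y)):
        Xtr, ytr = X[tr_idx], y[tr_idx]
        inner = StratifiedKFold(cv.k_inner, shuffle=True,
                                random_state=cv.seed + 1000 + fold_i)
        inner_folds = list(inner.split(Xtr, ytr))
        bookkeeping["outer"].append((tr_idx.tolist(), val_idx.tolist()))
        bookkeeping["inner"].append(
            [(tr_idx[a].tolist(), tr_idx[b].tolist()) for a, b in inner_folds]
        )
        scores = []
        for param in model.grid:
            accs = []
            for a, b in inner_folds:
                est = make_estimator(model.family, param, cv.seed)
                _fit(est, Xtr[a], ytr[a])
                accs.append(np.mean(est.predict(Xtr[b]) == ytr[b]))
            scores.append(np.mean(accs))
        best = model.grid[int(np.argmax(scores))]  # argmax keeps first (smallest) on ties
        chosen.append(best)
        est = make_estimator(model.family, best, cv.seed)
        _fit(est, Xtr, ytr)
        outer_train_acc.append(np.mean(est.predict(Xtr) == ytr))
        pred_val = est.predict(X[val_idx])
        outer_val_acc.append(np.mean(pred_val == y[val_idx]))
        cm_cv += _confusion(y[val_idx], pred_val, cv.positive_class)
    counts = Counter(chosen)
    top = max(counts.values())
    winners = [p for p in model.grid if counts.get(p, 0) == top]
    final_param = winners[0]  # grid order = ascending -> smallest wins ties
    fitted = make_estimator(model.family, final_param, cv.seed)
    _fit(fitted, X, y)
    report = CVReport(
        family=model.family,
        feature_subset=feature_subset,
        training_accuracy=float(np.mean(outer_train_acc)),
        outer_cv_accuracy=float(np.mean(outer_val_acc)),
        confusion_cv=cm_cv.tolist(),
        chosen_params=chosen,
        final_param=final_param,
        seed=cv.seed,
        fold_bookkeeping=bookkeeping,
    )
    return fitted, report


def evaluate(fitted, report: CVReport, test: FeatureTable, positive_class: str = "PD") -> CVReport:
    """Score the fitted model on the held-out table (counted on the table)."""
    labels_present = set(test.labels)
    if positive_class not in labels_present or len(labels_present) < 2:
        raise ValueError("test table must contain both classes")
    cols = feature_subset_columns(report.feature_subset)
    X = test.matrix(cols)
    test.eval_count += 1
    pred = fitted.predict(X)
    cm = _confusion(test.labels, pred, positive_class)
    m = metrics_from_confusion(cm)
    report.test_accuracy = m["accuracy"]
    report.sensitivity = m["sensitivity"]
    report.specificity = m["specificity"]
    report.f1 = m["f1"]
    report.confusion_test = cm.tolist()
    return report


def run_model_suite(
    train: FeatureTable, test: FeatureTable, cv: CVConfig,
    families: tuple = FAMILIES, subsets: tuple = FEATURE_SUBSETS,
) -> list[CVReport]:
    """The full experiment grid: 3 feature subsets x 3 model families.

    Per subset, z-score normalisation is fit on the training rows only
    and applied to both tables, using only that subset's columns.
    """
    reports = []
    for subset in subsets:
        cols = feature_subset_columns(subset)
        train.accessed_columns.update(cols)
        test.accessed_columns.update(cols)
        stats = zscore_fit(train.df, cols)
        train_z = FeatureTable(zscore_apply(train.df, stats), role="train",
                               seed=train.seed,
                               accessed_columns=train.accessed_columns)
        test_z = FeatureTable(zscore_apply(test.df, stats), role="test",
                              seed=test.seed,
                              accessed_columns=test.accessed_columns)
        for family in families:
            fitted, report = nested_cv_train(train_z, ModelSpec(family), cv, subset)
            report = evaluate(fitted, report, test_z, cv.positive_class)
            test.eval_count += test_z.eval_count
            test_z.eval_count = 0
            reports.append(report)
    return reports


def suite_to_frame(reports: list[CVReport]) -> pd.DataFrame:
    """Flat summary table (percent accuracies, unit-interval rates)."""
    rows = []
    for r in reports:
        rows.append({
            "feature_set": r.feature_subset,
            "model": r.family,
            "training_accuracy_pct": 100 * r.training_accuracy,
            "outer_cv_accuracy_pct": 100 * r.outer_cv_accuracy,
            "test_accuracy_pct": 100 * r.test_accuracy if r.test_accuracy is not None else None,
            "sensitivity": r.sensitivity,
            "specificity": r.specificity,
            "f1_score": r.f1,
        })
    return pd.DataFrame(rows)
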