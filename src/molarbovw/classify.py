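"""Cross-validated benchmarking of classical classifiers on BoVW histograms.

Six classifiers are compared under stratified 10-fold cross-validation:
logistic regression, an RBF-kernel SVM, a single-hidden-layer MLP
(100 ReLU units), a decision tree, gradient boosting and a random
forest.  All classifiers in one run share the identical fold assignment
so the comparison is paired, and every unstated hyperparameter is pinned
in :data:`CLASSIFIER_DEFAULTS` for reproducibility.

Accuracy is the headline metric; the per-fold accuracies, their
arithmetic mean and their population standard deviation are reported
per classifier, alongside a pooled out-of-fold confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError, ParameterError

__all__ = [
    "CLASSIFIER_DEFAULTS",
    "CLASSIFIER_NAMES",
    "CvResult",
    "make_folds",
    "train_classifier",
    "cross_validate",
    "results_to_frame",
]

#: Pinned hyperparameters for every classifier (the protocol names the
#: models, not their settings; these are the versioned defaults).
CLASSIFIER_DEFAULTS: dict[str, dict] = {
    "logistic_regression": {"C": 1.0, "max_iter": 2000},
    "svm_rbf": {"C": 1.0, "gamma": "scale"},
    "mlp": {
        "hidden_layer_sizes": (100,),
        "activation": "relu",
        "max_iter": 800,
        "alpha": 1e-4,
    },
    "decision_tree": {"criterion": "gini", "max_depth": None},
    "gradient_boosting": {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 3},
    "random_forest": {"n_estimators": 100, "max_features": "sqrt"},
}

CLASSIFIER_NAMES = tuple(CLASSIFIER_DEFAULTS)


@dataclass
class CvResult:
    """Per-classifier cross-validation outcome."""

    classifier_name: str
    fold_accuracies: list[float]
    fold_assignment: np.ndarray  # item index -> fold index
    seed: int
    failed_folds: list[int] = field(default_factory=list)
    confusion: np.ndarray | None = None
    class_order: tuple[str, ...] = ()

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std_accuracy(self) -> float:
        # population std over the fold accuracies
        return float(np.std(self.fold_accuracies))


def make_folds(labels: Sequence, n_folds: int = 10, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment: item index -> fold in [0, n_folds).

    Members of each class are dealt cyclically into a seeded random fold
    order with a global counter, so overall fold sizes differ by at most
    one and so do per-class counts across folds.  Works for any class
    count >= 1 (no minimum class size beyond one member).
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < n_folds:
        raise ConfigurationError(f"cannot make {n_folds} folds from {n} items")
    if n_folds < 2:
        raise ConfigurationError(f"n_folds must be >= 2, got {n_folds}")
    rng = np.random.default_rng(seed)
    fold_order = rng.permutation(n_folds)
    assignment = np.empty(n, dtype=np.int64)
    t = 0
    for cls in sorted(np.unique(labels).tolist()):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        for i in idx:
            assignment[i] = fold_order[t % n_folds]
            t += 1
    return assignment


def train_classifier(
    name: str,
    train_histograms: np.ndarray,
    train_labels: Sequence,
    hyper: dict | None = None,
    seed: int = 0,
):
    """Instantiate and fit one of the six benchmark classifiers."""
    if name not in CLASSIFIER_DEFAULTS:
        raise ParameterError(
            f"unknown classifier {name!r}; valid names: {list(CLASSIFIER_NAMES)}"
        )
    params = dict(CLASSIFIER_DEFAULTS[name])
    if hyper:
        params.update(hyper)
    if name == "logistic_regression":
        model = LogisticRegression(**params)
    elif name == "svm_rbf":
        model = SVC(kernel="rbf", random_state=seed, **params)
    elif name == "mlp":
        model = MLPClassifier(random_state=seed, **params)
    elif name == "decision_tree":
        model = DecisionTreeClassifier(random_state=seed, **params)
    elif name == "gradient_boosting":
        model = GradientBoostingClassifier(random_state=seed, **params)
    else:
        model = RandomForestClassifier(random_state=seed, **params)
    X = np.asarray(train_histograms, dtype=np.float64)
    if not np.isfinite(X).all():
        raise ParameterError("histograms contain non-finite values")
    model.fit(X, np.asarray(train_labels))
    return model


def cross_validate(
    histograms: np.ndarray,
    labels: Sequence,
    names: Sequence[str] = CLASSIFIER_NAMES,
    n_folds: int = 10,
    seed: int = 0,
    hyper: dict[str, dict] | None = None,
) -> list[CvResult]:
    """Paired k-fold comparison: one shared fold assignment, per-classifier
    fold accuracies.

    A training failure in one fold marks that fold failed for that
    classifier only; the remaining folds and classifiers are unaffected.
    """
    X = np.asarray(histograms, dtype=np.float64)
    y = np.asarray(labels)
    if X.shape[0] != len(y):
        raise ConfigurationError(f"{X.shape[0]} histograms but {len(y)} labels")
    assignment = make_folds(y, n_folds=n_folds, seed=seed)
    class_order = tuple(sorted(np.unique(y).tolist()))
    results = []
    for name in names:
        fold_acc: list[float] = []
        failed: list[int] = []
        oof_true: list[np.ndarray] = []
        oof_pred: list[np.ndarray] = []
        for fold in range(n_folds):
            test = assignment == fold
            try:
                model = train_classifier(
                    name, X[~test], y[~test], (hyper or {}).get(name), seed=seed
                )
                pred = model.predict(X[test])
            except Exception:
                failed.append(fold)
                fold_acc.append(float("nan"))
                continue
            fold_acc.append(float(np.mean(pred == y[test])))
            oof_true.append(y[test])
            oof_pred.append(pred)
        conf = None
        if oof_true:
            conf = confusion_matrix(
                np.concatenate(oof_true), np.concatenate(oof_pred), labels=class_order
            )
        results.append(
            CvResult(
                classifier_name=name,
                fold_accuracies=fold_acc,
                fold_assignment=assignment,
                seed=seed,
                failed_folds=failed,
                confusion=conf,
                class_order=class_order,
            )
        )
    return results


def results_to_frame(results_by_extractor: dict[str, list[CvResult]]) -> pd.DataFrame:
    """Summary table: rows = classifiers, columns = extractors,
    cells = ``mean±std`` accuracy (classifiers-by-extractors layout)."""
    frame: dict[str, dict[str, str]] = {}
    for extractor, results in results_by_extractor.items():
        for res in results:
            frame.setdefault(res.classifier_name, {})[extractor] = (
                f"{res.mean_accuracy:.3f}±{res.std_accuracy:.3f}"
            )
    return pd.DataFrame(frame).T.reindex(
        [n for n in CLASSIFIER_NAMES if n in frame]
    )
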