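"""SVM / decision-tree-bagger training and cross-validated evaluation.

Models follow the package's standard configuration: an RBF-kernel SVM with
one-versus-one multiclass decisions and C = 5 on standardized features, and
a bagged decision-tree ensemble (bootstrap replicas, random attribute
subsets at each split).  Evaluation uses stratified k-fold cross-validation;
all preprocessing (standardization, optional PCA) is fitted on the training
folds only.  Reported metrics are accuracy, AUC, sensitivity and precision
(macro-averaged one-vs-rest for multiclass problems) with per-fold values,
mean +/- std, and a pooled confusion matrix.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import confusion_matrix, precision_score, recall_score, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import DataError
from .fusion import Standardizer, pca_fit, pca_project, standardize_apply, standardize_fit

__all__ = [
    "SVMConfig",
    "DTBConfig",
    "FoldPlan",
    "MetricsReport",
    "make_folds",
    "train_svm",
    "train_dtb",
    "train_classifier",
    "predict_with_scores",
    "compute_metrics",
    "cross_validate",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class SVMConfig:
    """RBF-kernel support vector machine configuration.

    ``gamma='auto'`` is 1/n_features, the package default on standardized
    inputs; C defaults to 5.  Multiclass decisions are one-versus-one
    internally (the SMO-style dual solver of libsvm).
    """

    C: float = 5.0
    kernel: str = "rbf"
    gamma: float | str = "auto"

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")


@dataclasses.dataclass(frozen=True)
class DTBConfig:
    """Bagged decision-tree ensemble configuration.

    Defaults: 100 trees, sqrt(n_features) candidate attributes per split,
    bootstrap resampling with replacement.
    """

    n_trees: int = 100
    max_features: str | int | float = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclasses.dataclass(frozen=True)
class FoldPlan:
    """Fold index per sample for k-fold cross-validation."""

    k: int
    assignments: np.ndarray
    stratified: bool
    seed: int


@dataclasses.dataclass
class MetricsReport:
    """Per-fold and aggregated classification metrics.

    ``auc`` entries may be NaN when scores were unavailable for a fold.
    The confusion matrix is pooled over all test folds, rows = true class,
    columns = predicted class, in the order of ``class_labels``.
    """

    fold_acc: np.ndarray
    fold_auc: np.ndarray
    fold_sen: np.ndarray
    fold_prec: np.ndarray
    confusion: np.ndarray
    class_labels: tuple

    def _agg(self, values: np.ndarray) -> tuple[float, float]:
        return float(np.mean(values)), float(np.std(values))

    @property
    def acc_mean(self) -> float:
        return self._agg(self.fold_acc)[0]

    @property
    def acc_std(self) -> float:
        return self._agg(self.fold_acc)[1]

    @property
    def auc_mean(self) -> float:
        return float(np.nanmean(self.fold_auc))

    @property
    def sen_mean(self) -> float:
        return self._agg(self.fold_sen)[0]

    @property
    def prec_mean(self) -> float:
        return self._agg(self.fold_prec)[0]

    def summary(self) -> dict:
        return {
            "acc": {"mean": self.acc_mean, "std": self.acc_std,
                    "folds": self.fold_acc.tolist()},
            "auc": {"mean": self.auc_mean, "std": float(np.nanstd(self.fold_auc)),
                    "folds": self.fold_auc.tolist()},
            "sen": {"mean": self.sen_mean, "std": float(np.std(self.fold_sen)),
                    "folds": self.fold_sen.tolist()},
            "prec": {"mean": self.prec_mean, "std": float(np.std(self.fold_prec)),
                     "folds": self.fold_prec.tolist()},
            "confusion": self.confusion.tolist(),
            "classes": [str(c) for c in self.class_labels],
        }


def make_folds(labels, k: int, seed: int = 0, stratified: bool = True) -> FoldPlan:
    """Assign every sample to exactly one of ``k`` folds, deterministically.

    Stratified assignment keeps per-class fold sizes within one sample of
    each other.  If some class has fewer members than ``k`` a warning is
    emitted and plain (unstratified) splitting is used instead.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2 or k > n:
        raise ValueError(f"k={k} must be in 2..{n}")
    use_strat = stratified
    if stratified:
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < k:
            warnings.warn(
                f"smallest class has {counts.min()} < k={k} samples; "
                "falling back to unstratified folds",
                stacklevel=2,
            )
            use_strat = False
    assignments = np.empty(n, dtype=np.int64)
    if use_strat:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros((n, 1)), labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros((n, 1)))
    for fold, (_, test_idx) in enumerate(split):
        assignments[test_idx] = fold
    return FoldPlan(k=k, assignments=assignments, stratified=use_strat, seed=seed)


def _check_training_labels(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise DataError("training data contains a single class")


def train_svm(X, y, cfg: SVMConfig = SVMConfig()) -> SVC:
    """Fit the RBF SVM; expects standardized features."""
    y = np.asarray(y)
    _check_training_labels(y)
    model = SVC(
        C=cfg.C,
        kernel=cfg.kernel,
        gamma=cfg.gamma,
        decision_function_shape="ovr",
    )
    model.fit(np.asarray(X), y)
    return model


def train_dtb(X, y, cfg: DTBConfig = DTBConfig()) -> BaggingClassifier:
    """Fit the bagged decision-tree ensemble."""
    y = np.asarray(y)
    _check_training_labels(y)
    model = BaggingClassifier(
        estimator=DecisionTreeClassifier(max_features=cfg.max_features),
        n_estimators=cfg.n_trees,
        bootstrap=True,
        random_state=cfg.seed,
    )
    model.fit(np.asarray(X), y)
    return model


def train_classifier(X, y, cfg):
    if isinstance(cfg, SVMConfig):
        return train_svm(X, y, cfg)
    if isinstance(cfg, DTBConfig):
        return train_dtb(X, y, cfg)
    raise TypeError(f"unsupported classifier config {type(cfg).__name__}")


def predict_with_scores(model, X) -> tuple[np.ndarray, np.ndarray]:
    """Class predictions plus per-class scores usable for ROC curves.

    SVM scores are one-vs-rest decision values; bagged trees report class
    vote fractions.  For binary problems a (n, 2) score matrix is returned
    with columns ordered like ``model.classes_``.
    """
    X = np.asarray(X)
    pred = model.predict(X)
    if hasattr(model, "predict_proba"):
        scores = model.predict_proba(X)
    else:
        scores = model.decision_function(X)
        if scores.ndim == 1:
            scores = np.column_stack([-scores, scores])
    return pred, scores


def compute_metrics(
    y_true,
    y_pred,
    scores: np.ndarray | None = None,
    class_labels: Sequence | None = None,
    positive_label=None,
) -> dict:
    """Accuracy, AUC, sensitivity and precision for one evaluation.

    Binary problems use ``positive_label`` (default: the last class in
    sorted order) for sensitivity/precision/AUC; multiclass problems
    macro-average the one-vs-rest values.  ``scores`` must be (n, n_classes)
    with columns ordered like ``class_labels``; when absent, AUC is NaN.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if class_labels is None:
        class_labels = np.unique(y_true)
    class_labels = np.asarray(class_labels)
    n_classes = len(class_labels)
    acc = float(np.mean(y_true == y_pred))
    binary = n_classes == 2
    if binary:
        if positive_label is None:
            positive_label = class_labels[-1]
        sen = float(recall_score(y_true, y_pred, pos_label=positive_label,
                                 zero_division=0))
        prec = float(precision_score(y_true, y_pred, pos_label=positive_label,
                                     zero_division=0))
    else:
        sen = float(recall_score(y_true, y_pred, labels=class_labels,
                                 average="macro", zero_division=0))
        prec = float(precision_score(y_true, y_pred, labels=class_labels,
                                     average="macro", zero_division=0))
    auc = float("nan")
    if scores is not None:
        scores = np.asarray(scores)
        if scores.shape != (len(y_true), n_classes):
            raise DataError(
                f"scores shape {scores.shape} does not match "
                f"({len(y_true)}, {n_classes})"
            )
        if binary:
            col = int(np.flatnonzero(class_labels == positive_label)[0])
            auc = float(roc_auc_score(y_true == positive_label, scores[:, col]))
        else:
            aucs = []
            for col, label in enumerate(class_labels):
                mask = y_true == label
                if mask.any() and not mask.all():
                    aucs.append(roc_auc_score(mask, scores[:, col]))
            auc = float(np.mean(aucs)) if aucs else float("nan")
    confusion = confusion_matrix(y_true, y_pred, labels=class_labels)
    return {
        "acc": acc,
        "auc": auc,
        "sen": sen,
        "prec": prec,
        "confusion": confusion,
        "classes": tuple(class_labels.tolist()),
    }


def cross_validate(
    X,
    y,
    folds: FoldPlan,
    classifier_config=SVMConfig(),
    n_components: int | None = None,
    rotate: bool = True,
    positive_label=None,
) -> MetricsReport:
    """k-fold cross-validated evaluation with leakage-free preprocessing.

    Per fold: a :class:`~sheartex.fusion.Standardizer` (and optionally a
    varimax-rotated PCA with ``n_components``) is fitted on the training
    split only, the classifier is trained, and metrics are computed on the
    held-out fold.  Aggregates are the mean and standard deviation over the
    k folds; the confusion matrix pools all test predictions.
    """
    X = np.asarray(X, dtype=np.float64) if not hasattr(X, "X") else X.X
    y = np.asarray(y)
    if len(y) != X.shape[0]:
        raise DataError("labels do not align with feature rows")
    class_labels = np.unique(y)
    accs, aucs, sens, precs = [], [], [], []
    pooled = np.zeros((len(class_labels), len(class_labels)), dtype=np.int64)
    for fold in range(folds.k):
        test_mask = folds.assignments == fold
        X_train, y_train = X[~test_mask], y[~test_mask]
        X_test, y_test = X[test_mask], y[test_mask]
        scaler = standardize_fit(X_train)
        Z_train = standardize_apply(X_train, scaler)
        Z_test = standardize_apply(X_test, scaler)
        if n_components is not None:
            k_fit = min(n_components, Z_train.shape[1], Z_train.shape[0] - 1)
            model_pca = pca_fit(Z_train, k_fit, rotate=rotate)
            Z_train = pca_project(Z_train, model_pca)
            Z_test = pca_project(Z_test, model_pca)
        model = train_classifier(Z_train, y_train, classifier_config)
        pred, scores = predict_with_scores(model, Z_test)
        # align score columns with the global class order
        if scores.shape[1] == len(class_labels):
            order = [int(np.flatnonzero(model.classes_ == c)[0]) for c in class_labels]
            scores = scores[:, order]
        else:
            scores = None
        m = compute_metrics(y_test, pred, scores, class_labels, positive_label)
        accs.append(m["acc"])
        aucs.append(m["auc"])
        sens.append(m["sen"])
        precs.append(m["prec"])
        pooled += m["confusion"]
    return MetricsReport(
        fold_acc=np.array(accs),
        fold_auc=np.array(aucs),
        fold_sen=np.array(sens),
        fold_prec=np.array(precs),
        confusion=pooled,
        class_labels=tuple(class_labels.tolist()),
    )
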