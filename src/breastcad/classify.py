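"""SVM and Fisher-discriminant classification with case-level resampling.

Two classifiers discriminate benign from malignant masses from the
selected feature subset: a soft-margin SVM (RBF kernel by default,
optionally tuned by an inner cross-validated grid search — the "two
loop" scheme) and Fisher's linear discriminant.  Performance is
estimated by leave-one-case-out or repeated stratified half-split
("leave-half-case-out") resampling; standardisation statistics are
always fit on the training fold only.

Malignant is the positive class throughout, so sensitivity is the
detection rate of malignant masses and specificity the correct-
rejection rate of benign ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedShuffleSplit
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "ClassifierSpec",
    "EvalResult",
    "FisherModel",
    "fisher_train",
    "svm_train",
    "train_classifier",
    "confusion_metrics",
    "leave_one_case_out",
    "leave_half_case_out",
]

POSITIVE = "malignant"
NEGATIVE = "benign"

DEFAULT_C_GRID = tuple(2.0**e for e in range(-3, 8))
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-7, 4))


@dataclass
class ClassifierSpec:
    kind: str = "svm"  # svm | fisher
    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | str = "scale"
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.kind not in ("svm", "fisher"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")


@dataclass
class EvalResult:
    accuracy: float
    sensitivity: float
    specificity: float
    tp: int
    tn: int
    fp: int
    fn: int
    predictions: list[str] = field(default_factory=list)
    resampling: str = ""
    seed: int = 0
    per_repeat: list[dict] = field(default_factory=list)


class FisherModel:
    """Fisher linear discriminant: w = S_w^-1 (m1 - m0), midpoint cut."""

    def __init__(self, w: np.ndarray, threshold: float, flip: bool):
        self.w = w
        self.threshold = threshold
        self.flip = flip

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.w - self.threshold

    def predict(self, X: np.ndarray) -> np.ndarray:
        score = self.decision_function(X)
        pos = score >= 0 if not self.flip else score < 0
        return np.where(pos, POSITIVE, NEGATIVE)


def fisher_train(X, y, ridge: float = 1e-6) -> FisherModel:
    """Train Fisher's discriminant; a small ridge keeps S_w invertible."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim == 1:
        X = X[:, None]
    classes = set(y)
    if classes != {POSITIVE, NEGATIVE}:
        if len(classes) < 2:
            raise ValueError("both classes must be present to train")
        raise ValueError(f"unexpected labels {classes}")
    X1 = X[y == POSITIVE]
    X0 = X[y == NEGATIVE]
    m1 = X1.mean(axis=0)
    m0 = X0.mean(axis=0)
    S = (X1 - m1).T @ (X1 - m1) + (X0 - m0).T @ (X0 - m0)
    S = S + ridge * np.eye(X.shape[1]) * max(np.trace(S) / X.shape[1], 1.0)
    w = np.linalg.solve(S, m1 - m0)
    proj1 = X1 @ w
    proj0 = X0 @ w
    threshold = 0.5 * (proj1.mean() + proj0.mean())
    flip = proj1.mean() < proj0.mean()
    return FisherModel(w=w, threshold=threshold, flip=flip)


def svm_train(X, y, spec: ClassifierSpec | None = None) -> Pipeline:
    """Fit a soft-margin SVM (optionally standardised) pipeline."""
    spec = spec or ClassifierSpec()
    steps = []
    if spec.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(
        ("svm", SVC(kernel=spec.kernel, C=spec.C, gamma=spec.gamma))
    )
    model = Pipeline(steps)
    y = np.asarray(y)
    if len(set(y)) < 2:
        # Degenerate single-class fold: predict the present class.
        only = y[0]
        class _Constant:
            def predict(self, X):
                return np.full(len(np.asarray(X)), only, dtype=object)
        return _Constant()
    model.fit(np.asarray(X, dtype=float), y)
    return model


def train_classifier(X, y, spec: ClassifierSpec):
    if spec.kind == "fisher":
        if spec.standardize:
            scaler = StandardScaler().fit(np.asarray(X, dtype=float))
            inner = fisher_train(scaler.transform(np.asarray(X, dtype=float)), y)

            class _Wrapped:
                def predict(self, Xt):
                    return inner.predict(scaler.transform(np.asarray(Xt, dtype=float)))

            return _Wrapped()
        return fisher_train(X, y)
    return svm_train(X, y, spec)


def confusion_metrics(y_true: Sequence, y_pred: Sequence) -> EvalResult:
    """Accuracy, sensitivity and specificity with malignant positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    tp = int(((y_true == POSITIVE) & (y_pred == POSITIVE)).sum())
    tn = int(((y_true == NEGATIVE) & (y_pred == NEGATIVE)).sum())
    fp = int(((y_true == NEGATIVE) & (y_pred == POSITIVE)).sum())
    fn = int(((y_true == POSITIVE) & (y_pred == NEGATIVE)).sum())
    n = len(y_true)
    acc = (tp + tn) / n
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return EvalResult(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        predictions=list(y_pred),
    )


def _tune_svm(
    X_train: np.ndarray,
    y_train: np.ndarray,
    spec: ClassifierSpec,
    c_grid: Sequence[float],
    gamma_grid: Sequence[float],
    inner_folds: int = 5,
) -> ClassifierSpec:
    """Inner-loop grid search over (C, gamma) by cross-validation."""
    steps = []
    if spec.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("svm", SVC(kernel=spec.kernel)))
    grid = {"svm__C": list(c_grid)}
    if spec.kernel == "rbf":
        grid["svm__gamma"] = list(gamma_grid)
    counts = np.bincount(pd.factorize(y_train)[0])
    folds = int(min(inner_folds, counts.min()))
    if folds < 2:
        return spec
    search = GridSearchCV(Pipeline(steps), grid, cv=folds, n_jobs=None)
    search.fit(X_train, y_train)
    best = search.best_params_
    tuned = ClassifierSpec(
        kind="svm",
        kernel=spec.kernel,
        C=best["svm__C"],
        gamma=best.get("svm__gamma", spec.gamma),
        standardize=spec.standardize,
    )
    return tuned


def leave_one_case_out(
    X,
    y,
    spec: ClassifierSpec | None = None,
    inner_tuning: bool = False,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
) -> EvalResult:
    """Two-loop leave-one-case-out evaluation.

    The outer loop holds out each case once; when ``inner_tuning`` is
    on and the classifier is an SVM, an inner cross-validated grid
    search selects (C, gamma) on the remaining cases.  All training
    statistics (scaling, tuning) see only the training fold.
    """
    spec = spec or ClassifierSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < 2:
        raise ValueError("need at least two cases")
    preds = np.empty(n, dtype=object)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Xt, yt = X[keep], y[keep]
        fold_spec = spec
        if inner_tuning and spec.kind == "svm":
            fold_spec = _tune_svm(Xt, yt, spec, c_grid, gamma_grid)
        model = train_classifier(Xt, yt, fold_spec)
        preds[i] = model.predict(X[i : i + 1])[0]
    result = confusion_metrics(y, preds)
    result.resampling = "leave_one_case_out"
    return result


def leave_half_case_out(
    X,
    y,
    spec: ClassifierSpec | None = None,
    n_repeats: int = 100,
    seed: int = 0,
    inner_tuning: bool = False,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
) -> EvalResult:
    """Repeated stratified 50/50 split evaluation, metrics averaged.

    Each repeat trains on a random stratified half and tests on the
    other half; reported metrics are means over repeats, with the
    per-repeat results retained in ``per_repeat``.
    """
    spec = spec or ClassifierSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("each class needs at least two cases")

    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats, test_size=0.5, random_state=seed
    )
    per_repeat = []
    agg = np.zeros(3)
    counts4 = np.zeros(4, dtype=int)
    for train_idx, test_idx in splitter.split(X, y):
        fold_spec = spec
        if inner_tuning and spec.kind == "svm":
            fold_spec = _tune_svm(X[train_idx], y[train_idx], spec, c_grid, gamma_grid)
        model = train_classifier(X[train_idx], y[train_idx], fold_spec)
        res = confusion_metrics(y[test_idx], model.predict(X[test_idx]))
        per_repeat.append(
            {
                "accuracy": res.accuracy,
                "sensitivity": res.sensitivity,
                "specificity": res.specificity,
            }
        )
        agg += (res.accuracy, res.sensitivity, res.specificity)
        counts4 += (res.tp, res.tn, res.fp, res.fn)
    agg /= n_repeats
    result = EvalResult(
        accuracy=float(agg[0]),
        sensitivity=float(agg[1]),
        specificity=float(agg[2]),
        tp=int(counts4[0]),
        tn=int(counts4[1]),
        fp=int(counts4[2]),
        fn=int(counts4[3]),
        resampling=f"leave_half_case_out(n_repeats={n_repeats})",
        seed=seed,
        per_repeat=per_repeat,
    )
    return result
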