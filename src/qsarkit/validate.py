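"""Unbiased accuracy assessment: plain k-fold cross-validation, the double
(nested) CV loop around hyper-parameter optimization, and external/temporal
test-set evaluation.

Hyper-parameters selected on the same data used to estimate generalization
accuracy bias that estimate optimistically. The double CV loop removes the
bias: each outer fold is held out while the optimization runs — with its own
inner CV — only on the corresponding outer training portion; the reported
metrics are pooled over the outer test folds, on which no selection ever
looked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .data import Dataset
from .exceptions import NoDataError, NoResponseError
from .learners import CLASSIFICATION, BaseLearner, LearnerSpec, as_learner
from .optimize import ParamSpace, configure, cv_folds, derive_seed, optimize_learner


@dataclass
class ConfusionMatrix:
    """Actual x predicted counts in a fixed class order."""

    classes: tuple
    counts: np.ndarray

    @classmethod
    def from_predictions(cls, actual, predicted, classes) -> "ConfusionMatrix":
        m = _sk_confusion(actual, predicted, labels=list(classes))
        return cls(tuple(classes), m)

    def to_dict(self) -> dict:
        return {"classes": list(self.classes), "counts": self.counts.tolist()}


def metrics(actual, predicted, task: str, train_mean: float | None = None) -> dict:
    """Standard metric suite.

    Classification: accuracy, per-class precision/recall. Regression: RMSE,
    R^2 and Q^2 = 1 - PRESS/SS_tot where the reference mean is the training
    mean when supplied (the cross-validated convention), else the mean of
    ``actual``. A zero-variance reference yields ``None`` for R^2/Q^2 rather
    than a crash.
    """
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted differ in length")
    if len(actual) == 0:
        raise NoDataError("no examples to score")
    if task == CLASSIFICATION:
        out = {"accuracy": float(np.mean(actual == predicted))}
        precision, recall = {}, {}
        for c in dict.fromkeys(list(actual) + list(predicted)):
            pred_c = predicted == c
            act_c = actual == c
            precision[str(c)] = (
                float(np.mean(act_c[pred_c])) if pred_c.any() else None
            )
            recall[str(c)] = float(np.mean(pred_c[act_c])) if act_c.any() else None
        out["precision"] = precision
        out["recall"] = recall
        return out
    actual = actual.astype(float)
    predicted = predicted.astype(float)
    press = float(np.sum((actual - predicted) ** 2))
    out = {"rmse": float(np.sqrt(press / len(actual)))}
    ss_self = float(np.sum((actual - actual.mean()) ** 2))
    out["r2"] = 1.0 - press / ss_self if ss_self > 0 else None
    ref = actual.mean() if train_mean is None else float(train_mean)
    ss_ref = float(np.sum((actual - ref) ** 2))
    out["q2"] = 1.0 - press / ss_ref if ss_ref > 0 else None
    return out


@dataclass
class CVResult:
    """Pooled cross-validation outcome.

    Every example is predicted exactly once, from the fold where it was held
    out; pooled metrics are computed over that assembled prediction vector
    (the summation over the outer test folds), with per-fold metrics and —
    for double CV — the per-fold chosen hyper-parameters kept for audit.
    """

    task: str
    pooled_predictions: np.ndarray
    actual: np.ndarray
    fold_of_example: np.ndarray
    per_fold_metrics: list[dict]
    pooled_metrics: dict
    confusion: ConfusionMatrix | None = None
    fold_params: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "pooled_metrics": self.pooled_metrics,
            "per_fold_metrics": self.per_fold_metrics,
            "fold_of_example": self.fold_of_example.tolist(),
            "fold_params": self.fold_params,
            "confusion": self.confusion.to_dict() if self.confusion else None,
        }


def _run_folds(dataset: Dataset, fold_list, fit_fold) -> CVResult:
    """Shared fold loop: ``fit_fold(fold_index, train_subset)`` returns a
    fitted model (and optionally its chosen parameters)."""
    n = len(dataset)
    classification = dataset.task == CLASSIFICATION
    actual = (
        dataset.response_labels().to_numpy()
        if classification
        else dataset.y().to_numpy()
    )
    pooled = np.empty(n, dtype=object if classification else float)
    fold_of = np.full(n, -1, dtype=int)
    per_fold, fold_params = [], []
    for i, (tr, te) in enumerate(fold_list):
        fitted = fit_fold(i, dataset.subset(tr))
        model, params = fitted if isinstance(fitted, tuple) else (fitted, None)
        pred = model.predict(dataset.subset(te))
        pooled[te] = pred
        fold_of[te] = i
        train_mean = float(np.mean(dataset.y().to_numpy()[tr])) if not classification else None
        per_fold.append(metrics(actual[te], pred, dataset.task, train_mean=train_mean))
        if params is not None:
            fold_params.append(params)
    pooled_metrics = metrics(actual, pooled, dataset.task)
    confusion = None
    if classification:
        confusion = ConfusionMatrix.from_predictions(
            actual, pooled, dataset.response_schema.levels
        )
    return CVResult(
        dataset.task, pooled, actual, fold_of, per_fold, pooled_metrics,
        confusion, fold_params,
    )


def kfold_cv(spec, dataset: Dataset, folds: int = 5, seed: int = 0) -> CVResult:
    """Plain k-fold CV of one fixed configuration (stratified for
    classification), deterministic under the seed."""
    fold_list = cv_folds(dataset, folds, seed)

    def fit_fold(i, train_subset):
        return as_learner(spec, derive_seed(seed, "train", i)).fit(train_subset)

    return _run_folds(dataset, fold_list, fit_fold)


def double_cv(
    spec: LearnerSpec,
    space: ParamSpace | None = None,
    dataset: Dataset = None,
    outer_folds: int = 5,
    inner_folds: int = 5,
    seed: int = 0,
    **opt_kwargs,
) -> CVResult:
    """Nested CV: per outer fold, optimize hyper-parameters with an inner CV
    restricted to the outer training portion, refit on that full portion
    with the chosen parameters, and predict the held-out fold. Inner seeds
    derive from (seed, outer fold index), so inner partitions differ across
    outer folds. An empty space degenerates to plain k-fold CV."""
    fold_list = cv_folds(dataset, outer_folds, seed)

    def fit_fold(i, train_subset):
        inner_seed = derive_seed(seed, "inner", i)
        result = optimize_learner(
            spec,
            space,
            train_subset,
            folds=inner_folds,
            seed=inner_seed,
            **opt_kwargs,
        )
        chosen = configure(spec, result.best_params)
        model = as_learner(chosen, derive_seed(seed, "outer-train", i)).fit(train_subset)
        return model, dict(result.best_params)

    return _run_folds(dataset, fold_list, fit_fold)


def evaluate_external(model: BaseLearner, test: Dataset) -> dict:
    """Score a trained model on a separate (external or temporal) test set:
    the same metric suite as CV, with extra columns ignored."""
    if len(test) == 0:
        raise NoDataError("external test set is empty")
    if test.response_schema is None:
        raise NoResponseError("external test set has no response variable")
    pred = model.predict(test)
    classification = model.task_ == CLASSIFICATION
    actual = (
        test.response_labels().to_numpy() if classification else test.y().to_numpy()
    )
    out = metrics(actual, pred, model.task_)
    if classification:
        out["confusion"] = ConfusionMatrix.from_predictions(
            actual, pred, model.classes_
        ).to_dict()
    return out
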