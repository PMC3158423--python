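"""Learner families behind one uniform train/predict contract.

Five families — random forest (``rf``), support vector machine (``svm``),
single-hidden-layer neural network (``ann``), boosted trees (``boost``,
binary classification only) and partial least squares (``pls``, regression)
— plus a consensus combiner, all as scikit-learn-style estimators operating
on :class:`~qsarkit.data.Dataset` objects.

Every family runs the same preprocessing pipeline, whose state is learned on
the training set and stored with the model:

    impute missing values  ->  scale to [-1, 1] (svm/ann only, and the
    response too for ann regression)  ->  encode  ->  fit

At prediction time the incoming table is first harmonized to the training
schema (extra variables ignored, level orders realigned, types converted),
then pushed through the stored pipeline. Class priors, when given, reweight
the predicted class probabilities before the argmax, shifting the prediction
distribution toward up-weighted classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier

from . import ann as ann_mod
from . import pls as pls_mod
from .data import ENUMERATED, Dataset, harmonize_to_schema
from .exceptions import NoDataError, UnsupportedTaskError
from .preprocessing import MeanModeImputer, SymmetricScaler

CLASSIFICATION = "classification"
REGRESSION = "regression"


def encode_features(data: Dataset, one_hot: bool) -> np.ndarray:
    """Numeric design matrix from an imputed dataset.

    Enumerated features become 0/1 indicator columns (one per level, in level
    order) for the margin/gradient families, or integer level codes for the
    tree families.
    """
    cols = []
    for var in data.feature_schemas:
        col = data.df[var.name].to_numpy(dtype=float)
        if var.kind == ENUMERATED and one_hot:
            codes = col.astype(int)
            block = np.zeros((len(col), len(var.levels)))
            block[np.arange(len(col)), codes] = 1.0
            cols.append(block)
        else:
            cols.append(col.reshape(-1, 1))
    return np.hstack(cols) if cols else np.empty((len(data), 0))


class BaseLearner(BaseEstimator):
    """Shared pipeline: schema capture, imputation, scaling, encoding,
    prior-weighted prediction. Subclasses implement ``_fit_core`` and
    ``_predict_core`` on the encoded matrix."""

    _one_hot = False
    _scales_features = False
    _scales_response = False

    # subclasses define __init__ with explicit params (sklearn convention)

    def _check_task(self, task: str, n_classes: int) -> None:
        pass

    def fit(self, data: Dataset, y=None):
        if len(data) == 0:
            raise NoDataError("cannot train on an empty dataset")
        task = data.task  # raises NoResponseError when undeclared
        resp = data.response_schema
        self.schema_ = list(data.schema)
        self.task_ = task
        self.classes_ = resp.levels if resp.kind == ENUMERATED else None
        self._check_task(task, len(self.classes_ or ()))

        self.imputer_ = MeanModeImputer().fit(data)
        d = self.imputer_.transform(data)
        use_scaling = self._scales_features and getattr(self, "scale", True)
        if use_scaling:
            self.scaler_ = SymmetricScaler(
                scale_response=self._scales_response and task == REGRESSION
            ).fit(d)
            d = self.scaler_.transform(d)
        else:
            self.scaler_ = None

        X = encode_features(d, self._one_hot)
        self.n_features_in_ = X.shape[1]
        yv = d.y().to_numpy()
        if task == CLASSIFICATION:
            yv = yv.astype(int)
        self._fit_core(X, yv)
        return self

    # -- prediction ----------------------------------------------------------

    def preprocess(self, data: Dataset) -> Dataset:
        """Harmonize to the training schema and apply the stored imputation
        and scaling; the space in which the applicability domain lives."""
        d, _ = harmonize_to_schema(data, self.schema_)
        d = self.imputer_.transform(d)
        if self.scaler_ is not None:
            d = self.scaler_.transform(d)
        return d

    def _encoded(self, data: Dataset) -> np.ndarray:
        return encode_features(self.preprocess(data), self._one_hot)

    def predict_proba(self, data: Dataset) -> np.ndarray:
        """Class-probability rows (classification only), after prior
        reweighting; each row is non-negative and sums to one."""
        if self.task_ != CLASSIFICATION:
            raise UnsupportedTaskError("predict_proba requires a classification model")
        p = self._proba_core(self._encoded(data))
        priors = getattr(self, "class_priors", None)
        if priors:
            w = np.array([float(priors.get(lv, 1.0)) for lv in self.classes_])
            p = p * w
        p = np.clip(p, 0.0, None)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def predict(self, data: Dataset) -> np.ndarray:
        """Predicted class labels (classification) or response values."""
        if self.task_ == CLASSIFICATION:
            idx = np.argmax(self.predict_proba(data), axis=1)
            return np.array([self.classes_[i] for i in idx], dtype=object)
        yhat = np.asarray(self._predict_core(self._encoded(data)), dtype=float).ravel()
        if self.scaler_ is not None and self.scaler_.response_name_ is not None:
            yhat = self.scaler_.inverse_transform_response(yhat)
        return yhat

    # -- hooks ---------------------------------------------------------------

    def _fit_core(self, X: np.ndarray, y: np.ndarray) -> None:
        raise NotImplementedError

    def _predict_core(self, X: np.ndarray) -> np.ndarray:
        return self.model_.predict(X)

    def _proba_core(self, X: np.ndarray) -> np.ndarray:
        return self.model_.predict_proba(X)


class RFLearner(BaseLearner):
    """Bagged random-decision-tree ensemble.

    ``mtry`` is the number of active attributes drawn at each split (the
    family's main tuning knob); ``None`` uses sqrt(nAttr) for classification
    and all features for regression. Bootstrap sampling is always on, and the
    per-tree out-of-bag row sets remain available for permutation importance.
    """

    family = "rf"

    def __init__(self, n_trees=100, mtry=None, class_priors=None, random_state=0):
        self.n_trees = n_trees
        self.mtry = mtry
        self.class_priors = class_priors
        self.random_state = random_state

    def _fit_core(self, X, y):
        kw = dict(
            n_estimators=int(self.n_trees),
            random_state=self.random_state,
            bootstrap=True,
        )
        if self.mtry is not None:
            kw["max_features"] = int(np.clip(int(round(self.mtry)), 1, X.shape[1]))
        if self.task_ == CLASSIFICATION:
            self.model_ = RandomForestClassifier(**kw)
        else:
            self.model_ = RandomForestRegressor(**kw)
        self.model_.fit(X, y)


class SVMLearner(BaseLearner):
    """RBF-kernel support vector machine with libSVM-style [-1, 1] feature
    scaling built into the pipeline.

    ``C`` and ``gamma`` are the optimized hyper-parameters. ``p`` (the
    epsilon-tube width for regression), ``coeff`` and ``degree`` are wired
    through to the underlying engine for non-RBF kernels but are not
    optimized; ``nu`` is reserved.
    """

    family = "svm"
    _one_hot = True
    _scales_features = True

    def __init__(
        self,
        C=1.0,
        gamma=0.03125,
        kernel="rbf",
        p=0.1,
        nu=None,
        coeff=0.0,
        degree=3,
        class_priors=None,
        scale=True,
        random_state=0,
    ):
        self.C = C
        self.gamma = gamma
        self.kernel = kernel
        self.p = p
        self.nu = nu
        self.coeff = coeff
        self.degree = degree
        self.class_priors = class_priors
        self.scale = scale
        self.random_state = random_state

    def _fit_core(self, X, y):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            if self.task_ == CLASSIFICATION:
                self.model_ = SVC(
                    C=float(self.C),
                    gamma=float(self.gamma),
                    kernel=self.kernel,
                    coef0=float(self.coeff),
                    degree=int(self.degree),
                    probability=True,
                    random_state=self.random_state,
                )
            else:
                self.model_ = SVR(
                    C=float(self.C),
                    gamma=float(self.gamma),
                    kernel=self.kernel,
                    coef0=float(self.coeff),
                    degree=int(self.degree),
                    epsilon=float(self.p),
                )
            self.model_.fit(X, y)

    def _proba_core(self, X):
        # SVC's internal class order follows the numeric codes we trained on
        p = self.model_.predict_proba(X)
        order = np.argsort(self.model_.classes_)
        return p[:, order]


class ANNLearner(BaseLearner):
    """Single-hidden-layer neural network with validation-based early
    stopping and multi-restart initialization (see :mod:`qsarkit.ann`).

    Features are scaled to [-1, 1]; for regression the response is scaled
    too and predictions mapped back. With ``early_stop=False`` the
    training-score criterion ``epsilon`` governs stopping instead.
    """

    family = "ann"
    _one_hot = True
    _scales_features = True
    _scales_response = True

    def __init__(
        self,
        n_hidden=10,
        max_epochs=3000,
        eval_every=5,
        patience=5,
        n_restarts=1,
        epsilon=0.0,
        early_stop=True,
        scale=True,
        validation_fraction=0.2,
        learning_rate=0.01,
        class_priors=None,
        random_state=0,
    ):
        self.n_hidden = n_hidden
        self.max_epochs = max_epochs
        self.eval_every = eval_every
        self.patience = patience
        self.n_restarts = n_restarts
        self.epsilon = epsilon
        self.early_stop = early_stop
        self.scale = scale
        self.validation_fraction = validation_fraction
        self.learning_rate = learning_rate
        self.class_priors = class_priors
        self.random_state = random_state

    def _fit_core(self, X, y):
        classification = self.task_ == CLASSIFICATION
        self.model_, self.training_info_ = ann_mod.fit_mlp(
            X,
            y,
            classification,
            n_hidden=int(self.n_hidden),
            max_epochs=int(self.max_epochs),
            eval_every=int(self.eval_every),
            patience=int(self.patience),
            n_restarts=int(self.n_restarts),
            epsilon=float(self.epsilon),
            early_stop=bool(self.early_stop),
            validation_fraction=float(self.validation_fraction),
            learning_rate=float(self.learning_rate),
            seed=int(self.random_state),
            classes=np.arange(len(self.classes_)) if classification else None,
        )

    def _proba_core(self, X):
        p = self.model_.predict_proba(X)
        order = np.argsort(self.model_.classes_)
        return p[:, order]


class BoostLearner(BaseLearner):
    """Boosted depth-limited decision trees, binary classification only.

    ``max_depth`` bounds each weak tree's branching depth and ``n_trees``
    sets the ensemble size — the two optimized hyper-parameters.
    """

    family = "boost"

    def __init__(self, max_depth=3, n_trees=50, class_priors=None, random_state=0):
        self.max_depth = max_depth
        self.n_trees = n_trees
        self.class_priors = class_priors
        self.random_state = random_state

    def _check_task(self, task, n_classes):
        if task != CLASSIFICATION:
            raise UnsupportedTaskError("boosted trees support classification only")
        if n_classes != 2:
            raise UnsupportedTaskError(
                f"boosted trees are solely for binary classification (got {n_classes} classes)"
            )

    def _fit_core(self, X, y):
        self.model_ = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(
                max_depth=int(self.max_depth), random_state=self.random_state
            ),
            n_estimators=int(self.n_trees),
            random_state=self.random_state,
        )
        self.model_.fit(X, y)


class PLSLearner(BaseLearner):
    """Partial least squares regression (NIPALS); the number of latent
    components is the optimized hyper-parameter, bounded by nAttr - 1 in the
    encoded feature space."""

    family = "pls"
    _one_hot = True

    def __init__(self, n_components=2, random_state=0):
        self.n_components = n_components
        self.random_state = random_state

    def _check_task(self, task, n_classes):
        if task != REGRESSION:
            raise UnsupportedTaskError("PLS models a continuous response")

    def _fit_core(self, X, y):
        self.model_ = pls_mod.pls_fit(X, y, int(self.n_components))

    def _predict_core(self, X):
        return self.model_.predict(X).ravel()


class MajorityLearner(BaseLearner):
    """Baseline: most frequent class (with class-frequency probabilities) or
    the training mean. Useful as a dummy in validation tests."""

    family = "majority"

    def __init__(self, random_state=0):
        self.random_state = random_state

    def _fit_core(self, X, y):
        if self.task_ == CLASSIFICATION:
            counts = np.bincount(y, minlength=len(self.classes_)).astype(float)
            self.proba_ = counts / counts.sum()
        else:
            self.mean_ = float(np.mean(y))

    def _predict_core(self, X):
        return np.full(len(X), self.mean_)

    def _proba_core(self, X):
        return np.tile(self.proba_, (len(X), 1))


# -- consensus ----------------------------------------------------------------


def consensus_vote(
    votes: np.ndarray, probas: Sequence[np.ndarray | None]
) -> tuple[np.ndarray, np.ndarray]:
    """Combine member class votes: strict majority wins; a vote tie goes to
    the class with the greatest summed probability when every member supplies
    probabilities. With no probabilities the first member's vote stands and
    the row is flagged.

    ``votes`` is (n_members, n_examples) of class indices; each proba is
    (n_examples, n_classes) or None. Returns (predicted indices, tie flags).
    """
    m, n = votes.shape
    sizes = [int(votes.max()) + 1] + [p.shape[1] for p in probas if p is not None]
    n_classes = max(sizes)
    counts = np.zeros((n, n_classes))
    for j in range(m):
        counts[np.arange(n), votes[j]] += 1
    top = counts.max(axis=1, keepdims=True)
    tied = (counts == top).sum(axis=1) > 1
    pred = counts.argmax(axis=1)
    flags = np.zeros(n, dtype=bool)
    if tied.any():
        if all(p is not None for p in probas):
            sums = np.sum(probas, axis=0)
            pred[tied] = sums[tied].argmax(axis=1)
        else:
            pred[tied] = votes[0][tied]
            flags[tied] = True
    return pred, flags


class ConsensusLearner(BaseLearner):
    """Combine two or more member learners: arithmetic mean for regression;
    for classification majority vote, ties broken by the greatest sum of the
    members' class probabilities."""

    family = "consensus"

    def __init__(self, members=(), random_state=0):
        self.members = members
        self.random_state = random_state

    def fit(self, data: Dataset, y=None):
        if len(self.members) < 2:
            raise ValueError("consensus needs at least 2 members")
        built = [
            m.build(self.random_state + i) if isinstance(m, LearnerSpec) else clone(m)
            for i, m in enumerate(self.members)
        ]
        self.members_ = [m.fit(data) for m in built]
        return self._adopt(self.members_, data.task)

    def _adopt(self, fitted, task):
        tasks = {m.task_ for m in fitted}
        if len(tasks) != 1:
            raise UnsupportedTaskError("consensus members must share one task type")
        self.members_ = list(fitted)
        self.task_ = task
        first = fitted[0]
        self.schema_ = first.schema_
        self.classes_ = first.classes_
        if self.task_ == CLASSIFICATION:
            for m in fitted:
                if m.classes_ != self.classes_:
                    raise UnsupportedTaskError("consensus members must share class labels")
        return self

    @classmethod
    def from_fitted(cls, members: Sequence[BaseLearner]) -> "ConsensusLearner":
        obj = cls(members=list(members))
        return obj._adopt(list(members), members[0].task_)

    def _member_probas(self, data):
        out = []
        for m in self.members_:
            try:
                out.append(m.predict_proba(data))
            except (UnsupportedTaskError, AttributeError):
                out.append(None)
        return out

    def predict(self, data: Dataset, return_flags: bool = False):
        if self.task_ == REGRESSION:
            preds = np.mean([m.predict(data) for m in self.members_], axis=0)
            return (preds, np.zeros(len(preds), dtype=bool)) if return_flags else preds
        label_to_idx = {lv: i for i, lv in enumerate(self.classes_)}
        votes = np.array(
            [[label_to_idx[v] for v in m.predict(data)] for m in self.members_]
        )
        pred_idx, flags = consensus_vote(votes, self._member_probas(data))
        labels = np.array([self.classes_[i] for i in pred_idx], dtype=object)
        self.tie_flags_ = flags
        return (labels, flags) if return_flags else labels

    def predict_proba(self, data: Dataset) -> np.ndarray:
        if self.task_ != CLASSIFICATION:
            raise UnsupportedTaskError("predict_proba requires a classification model")
        probas = [p for p in self._member_probas(data) if p is not None]
        if not probas:
            raise UnsupportedTaskError("no consensus member exposes probabilities")
        p = np.mean(probas, axis=0)
        return p / p.sum(axis=1, keepdims=True)


# -- specs and the train/predict vocabulary -----------------------------------

FAMILY_CLASSES: dict[str, type] = {
    "rf": RFLearner,
    "svm": SVMLearner,
    "ann": ANNLearner,
    "boost": BoostLearner,
    "pls": PLSLearner,
    "consensus": ConsensusLearner,
    "majority": MajorityLearner,
}


@dataclass
class LearnerSpec:
    """A learner family plus its hyper-parameter settings."""

    family: str
    params: dict = dc_field(default_factory=dict)

    def build(self, seed: int = 0) -> BaseLearner:
        try:
            cls = FAMILY_CLASSES[self.family]
        except KeyError:
            raise ValueError(f"unknown learner family {self.family!r}") from None
        return cls(**self.params, random_state=seed)


def as_learner(spec, seed: int = 0) -> BaseLearner:
    """Materialize a LearnerSpec, or re-seed a prototype estimator."""
    if isinstance(spec, LearnerSpec):
        return spec.build(seed)
    est = clone(spec)
    if "random_state" in est.get_params():
        est.set_params(random_state=seed)
    return est


def train(spec, data: Dataset, seed: int = 0) -> BaseLearner:
    """Train one learner (a LearnerSpec or an estimator prototype) on a
    dataset; a fixed seed makes the result reproducible bit-exactly."""
    return as_learner(spec, seed).fit(data)


def train_consensus(members, data: Dataset, seed: int = 0) -> ConsensusLearner:
    """Fit a consensus of specs/prototypes, or wrap already-fitted members."""
    if all(isinstance(m, BaseLearner) and hasattr(m, "task_") for m in members):
        return ConsensusLearner.from_fitted(list(members))
    return ConsensusLearner(members=list(members), random_state=seed).fit(data)
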