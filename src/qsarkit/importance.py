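"""Out-of-bag permutation variable importance for the random forest.

Each bagged tree leaves out a bootstrap-excluded (out-of-bag, OOB) set of
training rows, giving the ensemble a built-in validation sample per tree.
A variable's importance is the mean increase in a tree's OOB error when that
variable's values are randomly permuted *within the tree's OOB rows only* —
in-bag cells are untouched, and each tree is scored on its own OOB set with
and without the permutation. Uninformative variables shuffle to importances
scattered around zero (negative values are noise); informative ones degrade
the error when destroyed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .data import Dataset
from .exceptions import UnsupportedModelError
from .learners import CLASSIFICATION, RFLearner


@dataclass
class ImportanceResult:
    """Per-feature raw importances (mean OOB error increase), their ranks
    (1 = most important), per-tree standard errors, and provenance."""

    features: list[str]
    importances: np.ndarray
    ranks: np.ndarray
    se: np.ndarray
    per_tree: np.ndarray  # (n_trees, n_features) error increases
    n_trees: int
    seed: int

    def top(self, k: int) -> list[str]:
        order = np.argsort(-self.importances, kind="stable")
        return [self.features[i] for i in order[:k]]


def _fast_predict(tree, X32: np.ndarray, classification: bool) -> np.ndarray:
    out = tree.tree_.predict(X32)
    out = out.reshape(len(X32), -1)  # (n, n_classes) or (n, 1)
    if classification:
        return np.argmax(out, axis=1)
    return out[:, 0]


def oob_importance(
    rf_model: RFLearner,
    train: Dataset,
    seed: int = 0,
    n_repeats: int = 1,
) -> ImportanceResult:
    """Permutation importance from a fitted forest and its training set.

    Error is the misclassification rate for classification and the MSE for
    regression; one permutation per (tree, feature) by default, with
    ``n_repeats`` available for variance reduction. The permutation RNG is
    seeded, so results are reproducible.
    """
    if not isinstance(rf_model, RFLearner) or not hasattr(rf_model, "model_"):
        raise UnsupportedModelError(
            "OOB importance needs a fitted random-forest learner"
        )
    forest = rf_model.model_
    if not getattr(forest, "bootstrap", False):
        raise UnsupportedModelError("the forest must be trained with bootstrap sampling")

    X = rf_model._encoded(train)  # forest encoding: one column per feature
    classification = rf_model.task_ == CLASSIFICATION
    if classification:
        levels = list(rf_model.classes_)
        y = train.response_labels().map(levels.index).to_numpy()
    else:
        y = train.y().to_numpy(dtype=float)
    n, p = X.shape
    feats = train.feature_names

    rng = np.random.default_rng(seed)
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    diffs = []
    # tree.classes_ indexes into the forest's class set; map tree output -> y codes
    class_map = None
    if classification:
        class_map = np.asarray(forest.classes_)

    for tree, in_bag in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.ones(n, dtype=bool)
        oob[in_bag] = False
        idx = np.flatnonzero(oob)
        if idx.size == 0:
            continue
        Xo = X32[idx]
        yo = y[idx]
        pred = _fast_predict(tree, Xo, classification)
        if classification:
            base = float(np.mean(class_map[pred] != yo))
        else:
            base = float(np.mean((pred - yo) ** 2))
        row = np.zeros(p)
        for j in range(p):
            errs = []
            for _ in range(n_repeats):
                perm = rng.permutation(idx.size)
                Xp = Xo.copy()
                Xp[:, j] = Xo[perm, j]
                pp = _fast_predict(tree, Xp, classification)
                if classification:
                    errs.append(float(np.mean(class_map[pp] != yo)))
                else:
                    errs.append(float(np.mean((pp - yo) ** 2)))
            row[j] = float(np.mean(errs)) - base
        diffs.append(row)

    per_tree = np.asarray(diffs)
    importances = per_tree.mean(axis=0)
    se = per_tree.std(axis=0, ddof=1) / np.sqrt(len(per_tree))
    order = np.argsort(-importances, kind="stable")
    ranks = np.empty(p, dtype=int)
    ranks[order] = np.arange(1, p + 1)
    return ImportanceResult(
        feats, importances, ranks, se, per_tree, len(per_tree), seed
    )


def oob_scorer(n_trees: int = 500, seed: int = 0) -> Callable[[Dataset], np.ndarray]:
    """A feature scorer (Dataset -> importance vector) that trains a forest
    and returns its OOB permutation importances; usable inside wrapper
    feature selection."""

    def score(dataset: Dataset) -> np.ndarray:
        model = RFLearner(n_trees=n_trees, random_state=seed).fit(dataset)
        return oob_importance(model, dataset, seed=seed).importances

    return score


def rank_then_select(
    dataset: Dataset,
    scorer: Callable[[Dataset], np.ndarray] | Sequence[float],
    keep: int | float,
) -> Dataset:
    """Retain the top-``keep`` features by score, preserving response and
    meta columns. ``keep`` may be a count or a fraction in (0, 1); a count
    above the feature total is clipped with a warning."""
    scores = np.asarray(scorer(dataset) if callable(scorer) else scorer, dtype=float)
    p = dataset.n_attr
    if scores.shape[0] != p:
        raise ValueError("scorer returned a vector of the wrong length")
    if isinstance(keep, float) and 0 < keep < 1:
        k = max(1, int(round(keep * p)))
    else:
        k = int(keep)
    if k < 1:
        raise ValueError("keep must retain at least one feature")
    if k > p:
        warnings.warn(f"keep={k} exceeds the {p} available features; keeping all", stacklevel=2)
        k = p
    order = np.argsort(-scores, kind="stable")[:k]
    names = [dataset.feature_names[i] for i in sorted(order)]
    return dataset.select_features(names)
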