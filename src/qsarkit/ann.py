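"""Neural-network training protocol: validation-based early stopping and
multi-restart selection.

The network itself is a single-hidden-layer perceptron (scikit-learn's MLP
driven one epoch at a time through ``partial_fit``); the contribution here is
the training protocol wrapped around it:

* 20% of the training data is held out by stratified random sampling as a
  validation set, left outside the weight updates;
* validation accuracy is evaluated every ``eval_every`` (default 5) epochs;
* training halts when ``patience`` (default 5) consecutive evaluations fail
  to improve on the best seen, or at ``max_epochs`` (default 3000);
* the weights snapshot with the best validation accuracy is the model
  returned;
* optionally several networks are trained from different weight
  initializations (seeds ``seed``, ``seed+1``, ...); the one with the best
  validation accuracy wins, ties going to the network that trained for the
  fewest epochs, then to the lowest seed.

"Accuracy" means classification accuracy for classifiers and negative RMSE
for regression, so that higher is always better.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import ShuffleSplit, StratifiedShuffleSplit
from sklearn.neural_network import MLPClassifier, MLPRegressor


@dataclass
class EarlyStopResult:
    """Outcome of one early-stopped training run."""

    halt_epoch: int
    best_epoch: int
    best_value: float
    best_state: object
    trace: list[tuple[int, float]] = field(default_factory=list)


def run_early_stopping(
    train_epoch: Callable[[], None],
    evaluate: Callable[[], float],
    snapshot: Callable[[], object],
    eval_every: int = 5,
    patience: int = 5,
    max_epochs: int = 3000,
) -> EarlyStopResult:
    """Drive epoch-wise training under the early-stopping rule.

    ``train_epoch`` advances the model by one epoch; ``evaluate`` returns the
    current validation score (higher is better); ``snapshot`` captures the
    current weights and is called only when a new best score appears. The
    loop halts when ``patience`` consecutive evaluations fail to beat the
    best score seen (strict improvement required), or at ``max_epochs``.
    """
    best = -math.inf
    best_state = None
    best_epoch = 0
    fails = 0
    trace: list[tuple[int, float]] = []
    epoch = 0
    while epoch < max_epochs:
        epoch += 1
        train_epoch()
        if epoch % eval_every == 0:
            value = float(evaluate())
            trace.append((epoch, value))
            if value > best:
                best, best_epoch, best_state, fails = value, epoch, snapshot(), 0
            else:
                fails += 1
                if fails >= patience:
                    break
    return EarlyStopResult(epoch, best_epoch, best, best_state, trace)


def select_restart(results: Sequence[tuple[float, int]]) -> int:
    """Pick the winning restart from (validation accuracy, iterations) pairs.

    Best accuracy wins; an exact accuracy tie goes to the smallest number of
    training iterations; a remaining tie goes to the earliest restart (the
    lowest initialization seed). Returns the winner's index.
    """
    best = 0
    for i in range(1, len(results)):
        acc_i, it_i = results[i]
        acc_b, it_b = results[best]
        if acc_i > acc_b or (acc_i == acc_b and it_i < it_b):
            best = i
    return best


def split_validation(
    y: np.ndarray,
    classification: bool,
    fraction: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """80/20-style split: stratified by class for classification, random for
    regression. A class too small to stratify triggers a warning and a plain
    random split."""
    n = len(y)
    idx = np.arange(n)
    if classification:
        try:
            splitter = StratifiedShuffleSplit(
                n_splits=1, test_size=fraction, random_state=seed
            )
            tr, va = next(splitter.split(idx.reshape(-1, 1), y))
            return tr, va
        except ValueError:
            warnings.warn(
                "a class is too small for stratified sampling; "
                "falling back to a plain random validation split",
                stacklevel=2,
            )
    splitter = ShuffleSplit(n_splits=1, test_size=fraction, random_state=seed)
    tr, va = next(splitter.split(idx.reshape(-1, 1)))
    return tr, va


def _score(mlp, X, y, classification: bool) -> float:
    if classification:
        return float(np.mean(mlp.predict(X) == y))
    resid = mlp.predict(X).reshape(len(y), -1) - np.asarray(y).reshape(len(y), -1)
    return -float(np.sqrt(np.mean(resid**2)))


def _snapshot(mlp):
    return (copy.deepcopy(mlp.coefs_), copy.deepcopy(mlp.intercepts_))


def _restore(mlp, state):
    mlp.coefs_, mlp.intercepts_ = state


def fit_mlp(
    X: np.ndarray,
    y: np.ndarray,
    classification: bool,
    n_hidden: int = 10,
    max_epochs: int = 3000,
    eval_every: int = 5,
    patience: int = 5,
    n_restarts: int = 1,
    epsilon: float = 0.0,
    early_stop: bool = True,
    validation_fraction: float = 0.2,
    learning_rate: float = 0.01,
    seed: int = 0,
    classes: np.ndarray | None = None,
):
    """Train the perceptron under the full protocol; returns (mlp, info).

    One validation split, drawn from the master seed, is shared across all
    restarts so their scores are comparable. With ``early_stop=False`` the
    stopping rule is the training-score criterion instead: halt when the
    per-epoch improvement in training score drops below ``epsilon``, and
    restarts are compared on the training score.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if early_stop:
        tr, va = split_validation(y, classification, validation_fraction, seed)
    else:
        tr = va = np.arange(len(y))
    Xtr, ytr, Xva, yva = X[tr], y[tr], X[va], y[va]

    results: list[tuple[float, int]] = []
    candidates = []
    for r in range(n_restarts):
        mlp_cls = MLPClassifier if classification else MLPRegressor
        mlp = mlp_cls(
            hidden_layer_sizes=(n_hidden,),
            solver="adam",
            learning_rate_init=learning_rate,
            random_state=seed + r,
            max_iter=1,
        )

        def train_epoch(mlp=mlp):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # per-epoch convergence noise
                if classification:
                    mlp.partial_fit(Xtr, ytr, classes=classes)
                else:
                    mlp.partial_fit(Xtr, ytr)

        if early_stop:
            res = run_early_stopping(
                train_epoch,
                lambda mlp=mlp: _score(mlp, Xva, yva, classification),
                lambda mlp=mlp: _snapshot(mlp),
                eval_every=eval_every,
                patience=patience,
                max_epochs=max_epochs,
            )
            if res.best_state is not None:
                _restore(mlp, res.best_state)
            results.append((res.best_value, res.best_epoch))
            candidates.append((mlp, res))
        else:
            prev = -math.inf
            epoch = 0
            while epoch < max_epochs:
                epoch += 1
                train_epoch()
                score = _score(mlp, Xtr, ytr, classification)
                if epoch > 1 and score - prev < epsilon:
                    break
                prev = score
            res = EarlyStopResult(epoch, epoch, _score(mlp, Xtr, ytr, classification), None)
            results.append((res.best_value, res.halt_epoch))
            candidates.append((mlp, res))

    winner = select_restart(results)
    return candidates[winner][0], {
        "restart": winner,
        "halt_epoch": candidates[winner][1].halt_epoch,
        "best_epoch": candidates[winner][1].best_epoch,
        "validation_score": results[winner][0],
        "n_restarts": n_restarts,
    }
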