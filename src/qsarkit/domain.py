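"""Applicability-domain assessment by Mahalanobis distance in descriptor space.

A prediction is only as trustworthy as the query's proximity to the training
set. The domain model stores the training reference — either the set's
center or, in nearest-neighbor mode, the training rows themselves — together
with the (ridge-regularized) inverse covariance, and measures each query's
Mahalanobis distance. Calibrating on an external test set yields the first
and third quartiles of its distance distribution: a query at or below Q1 is
*inside* the domain, at or above Q3 its prediction is *unreliable*, and in
between it is *intermediate*.

Distances are computed in the model's preprocessing space (after imputation
and scaling, continuous encoded features) when fitted through a trained
learner; :func:`fit_domain` also accepts a plain numeric matrix.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .data import Dataset
from .exceptions import NoDataError, UncalibratedDomainError
from .learners import BaseLearner, encode_features

INSIDE = "inside"
INTERMEDIATE = "intermediate"
UNRELIABLE = "unreliable"


class MahalanobisDomain(BaseEstimator):
    """Mahalanobis applicability domain.

    Parameters
    ----------
    mode : {"center", "knn"}
        Reference for the training set: its mean vector, or the mean
        Mahalanobis distance to the ``k`` nearest training rows (nearness
        measured by the same metric).
    k : int
        Neighbor count for knn mode (clipped to the training size).
    ridge : float
        Covariance regularization strength; the stored inverse is of
        ``Sigma + ridge * trace(Sigma)/d * I``, which keeps collinear
        descriptor sets invertible.
    """

    def __init__(self, mode: str = "center", k: int = 3, ridge: float = 1e-6):
        self.mode = mode
        self.k = k
        self.ridge = ridge

    def fit(self, X: np.ndarray, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise NoDataError("domain fitting needs at least 2 training rows")
        if self.mode not in ("center", "knn"):
            raise ValueError(f"unknown domain mode {self.mode!r}")
        self.X_ = X
        self.mean_ = X.mean(axis=0)
        d = X.shape[1]
        sigma = np.cov(X, rowvar=False).reshape(d, d)
        lam = self.ridge * np.trace(sigma) / d if d else 0.0
        self.cov_inv_ = np.linalg.inv(sigma + lam * np.eye(d))
        self.k_ = int(min(self.k, X.shape[0]))
        if self.mode == "knn" and self.k > X.shape[0]:
            warnings.warn(
                f"k={self.k} exceeds the training size; clipped to {self.k_}",
                stacklevel=2,
            )
        self.q1_ = None
        self.q3_ = None
        return self

    # -- distances -----------------------------------------------------------

    def _mahal_to_rows(self, x: np.ndarray, rows: np.ndarray) -> np.ndarray:
        diff = rows - x
        return np.sqrt(np.einsum("ij,jk,ik->i", diff, self.cov_inv_, diff).clip(min=0.0))

    def distance(self, x: np.ndarray) -> float:
        """Mahalanobis distance of one query vector to the training reference."""
        x = np.asarray(x, dtype=float).ravel()
        if x.shape[0] != self.mean_.shape[0]:
            raise ValueError(
                f"query has {x.shape[0]} features, the domain expects {self.mean_.shape[0]}"
            )
        if self.mode == "center":
            diff = x - self.mean_
            return float(np.sqrt(max(diff @ self.cov_inv_ @ diff, 0.0)))
        d_all = self._mahal_to_rows(x, self.X_)
        return float(np.sort(d_all)[: self.k_].mean())

    def distances(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.mode == "center":
            diff = X - self.mean_
            return np.sqrt(
                np.einsum("ij,jk,ik->i", diff, self.cov_inv_, diff).clip(min=0.0)
            )
        return np.array([self.distance(x) for x in X])

    # -- calibration and assessment -------------------------------------------

    def calibrate(self, X_external: np.ndarray):
        """Set the quartile thresholds from an external test set's distances
        (linear-interpolation quantiles over the order statistics)."""
        X_external = np.asarray(X_external, dtype=float)
        if X_external.shape[0] < 4:
            raise NoDataError("calibration needs at least 4 external examples")
        d = self.distances(X_external)
        self.calibration_distances_ = d
        self.q1_ = float(np.quantile(d, 0.25))  # linear interpolation rule
        self.q3_ = float(np.quantile(d, 0.75))
        return self

    def assess(self, x: np.ndarray) -> tuple[str, float]:
        """Classify one query's reliability; boundaries are inclusive on both
        quartiles (d == Q1 is inside, d == Q3 is unreliable)."""
        if self.q1_ is None:
            raise UncalibratedDomainError("call calibrate() before assess()")
        d = self.distance(x)
        if d <= self.q1_:
            return INSIDE, d
        if d >= self.q3_:
            return UNRELIABLE, d
        return INTERMEDIATE, d

    def assess_many(self, X: np.ndarray) -> tuple[list[str], np.ndarray]:
        if self.q1_ is None:
            raise UncalibratedDomainError("call calibrate() before assess()")
        d = self.distances(X)
        labels = np.where(d <= self.q1_, INSIDE, np.where(d >= self.q3_, UNRELIABLE, INTERMEDIATE))
        return list(labels), d

    # -- persistence helpers ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "k": self.k,
            "ridge": self.ridge,
            "mean": self.mean_.tolist(),
            "cov_inv": self.cov_inv_.tolist(),
            "X": self.X_.tolist() if self.mode == "knn" else None,
            "q1": self.q1_,
            "q3": self.q3_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MahalanobisDomain":
        obj = cls(mode=d["mode"], k=d["k"], ridge=d["ridge"])
        obj.mean_ = np.asarray(d["mean"], dtype=float)
        obj.cov_inv_ = np.asarray(d["cov_inv"], dtype=float)
        obj.X_ = np.asarray(d["X"], dtype=float) if d.get("X") is not None else obj.mean_.reshape(1, -1)
        obj.k_ = int(min(d["k"], len(obj.X_)))
        obj.q1_ = d["q1"]
        obj.q3_ = d["q3"]
        return obj


def model_space(model: BaseLearner, data: Dataset) -> np.ndarray:
    """A dataset mapped into a trained model's preprocessing space."""
    return encode_features(model.preprocess(data), model._one_hot)


def fit_domain(
    train, mode: str = "center", k: int = 3, model: BaseLearner | None = None
) -> MahalanobisDomain:
    """Fit the applicability domain on training data.

    ``train`` may be a numeric matrix, or a :class:`Dataset` together with a
    trained ``model`` whose preprocessing space defines the descriptor
    coordinates.
    """
    if isinstance(train, Dataset):
        if model is None:
            raise ValueError("fitting a domain on a Dataset needs the trained model")
        X = model_space(model, train)
    else:
        X = np.asarray(train, dtype=float)
    return MahalanobisDomain(mode=mode, k=k).fit(X)


def correlation_report(
    distances: Sequence[float], abs_errors: Sequence[float]
) -> dict:
    """Pearson and Spearman correlation between distance and |prediction
    error| on a calibration set — a diagnostic of whether distance tracks
    reliability for this model."""
    d = np.asarray(distances, dtype=float)
    e = np.asarray(abs_errors, dtype=float)
    if d.std() == 0 or e.std() == 0:
        return {"pearson": None, "spearman": None, "n": int(len(d))}
    return {
        "pearson": float(stats.pearsonr(d, e).statistic),
        "spearman": float(stats.spearmanr(d, e).statistic),
        "n": int(len(d)),
    }
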