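"""Missing-value imputation and libSVM-style [-1, 1] feature scaling.

Both transformers learn their state from the training set and reuse it
verbatim on later data, including examples arriving at prediction time.
They are scikit-learn-style estimators operating on :class:`~qsarkit.data.Dataset`
objects (trailing-underscore fitted attributes, ``fit``/``transform``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .data import CONTINUOUS, Dataset
from .exceptions import UnfittableFeatureError


class MeanModeImputer(TransformerMixin, BaseEstimator):
    """Fill missing feature cells with the training mean (continuous) or the
    training mode (enumerated).

    Mode ties are broken toward the earliest level in schema order. Fill
    values come from the training set even when imputing new examples, and
    applying the transform twice equals applying it once.
    """

    def fit(self, data: Dataset, y=None):
        fills: dict[str, float] = {}
        for var in data.feature_schemas:
            col = data.df[var.name].to_numpy()
            ok = col[~np.isnan(col)]
            if ok.size == 0:
                raise UnfittableFeatureError(
                    f"feature {var.name!r} is entirely missing in the training set"
                )
            if var.kind == CONTINUOUS:
                fills[var.name] = float(np.mean(ok))
            else:
                counts = np.bincount(ok.astype(int), minlength=len(var.levels))
                fills[var.name] = float(np.argmax(counts))  # argmax: first max wins
        self.fill_values_ = fills
        return self

    def transform(self, data: Dataset) -> Dataset:
        df = data.df.copy()
        for name, fill in self.fill_values_.items():
            if name in df.columns:
                df[name] = df[name].fillna(fill)
        return Dataset(list(data.schema), df)

    def to_dict(self) -> dict:
        return {"fill_values": self.fill_values_}

    @classmethod
    def from_dict(cls, d: dict) -> "MeanModeImputer":
        m = cls()
        m.fill_values_ = {k: float(v) for k, v in d["fill_values"].items()}
        return m


class SymmetricScaler(TransformerMixin, BaseEstimator):
    """Affine rescaling of continuous features onto [-1, 1].

    Uses the libSVM convention: x' = -1 + 2 (x - min) / (max - min) with the
    per-feature extrema observed on the training set. Values outside the
    training range extrapolate beyond [-1, 1] with the same affine map, and
    a constant training feature (min == max) maps to 0 everywhere. With
    ``scale_response=True`` (used by the neural-network learner for
    regression) the response column is rescaled the same way and predictions
    can be mapped back with :meth:`inverse_transform_response`.
    """

    def __init__(self, scale_response: bool = False):
        self.scale_response = scale_response

    def _columns(self, data: Dataset) -> list[str]:
        cols = [v.name for v in data.feature_schemas if v.kind == CONTINUOUS]
        if self.scale_response:
            resp = data.response_schema
            if resp is not None and resp.kind == CONTINUOUS:
                cols.append(resp.name)
        return cols

    def fit(self, data: Dataset, y=None):
        mins: dict[str, float] = {}
        maxs: dict[str, float] = {}
        for name in self._columns(data):
            col = data.df[name].to_numpy()
            col = col[~np.isnan(col)]
            mins[name] = float(np.min(col))
            maxs[name] = float(np.max(col))
        self.min_ = mins
        self.max_ = maxs
        resp = data.response_schema
        self.response_name_ = resp.name if (self.scale_response and resp is not None) else None
        return self

    @staticmethod
    def _forward(x: pd.Series, lo: float, hi: float) -> pd.Series:
        if hi == lo:
            return pd.Series(np.where(np.isnan(x), np.nan, 0.0), index=x.index)
        return -1.0 + 2.0 * (x - lo) / (hi - lo)

    def transform(self, data: Dataset) -> Dataset:
        df = data.df.copy()
        for name, lo in self.min_.items():
            if name in df.columns:
                df[name] = self._forward(df[name], lo, self.max_[name])
        return Dataset(list(data.schema), df)

    def inverse_transform(self, data: Dataset) -> Dataset:
        """Undo the affine map (constant features recover their training value)."""
        df = data.df.copy()
        for name, lo in self.min_.items():
            if name not in df.columns:
                continue
            hi = self.max_[name]
            if hi == lo:
                df[name] = np.where(np.isnan(df[name]), np.nan, lo)
            else:
                df[name] = lo + (df[name] + 1.0) * (hi - lo) / 2.0
        return Dataset(list(data.schema), df)

    def inverse_transform_response(self, y_scaled: np.ndarray) -> np.ndarray:
        name = self.response_name_
        if name is None or name not in self.min_:
            return y_scaled
        lo, hi = self.min_[name], self.max_[name]
        if hi == lo:
            return np.full_like(np.asarray(y_scaled, dtype=float), lo)
        return lo + (np.asarray(y_scaled, dtype=float) + 1.0) * (hi - lo) / 2.0

    def to_dict(self) -> dict:
        return {
            "scale_response": self.scale_response,
            "min": self.min_,
            "max": self.max_,
            "response_name": self.response_name_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SymmetricScaler":
        m = cls(scale_response=d["scale_response"])
        m.min_ = {k: float(v) for k, v in d["min"].items()}
        m.max_ = {k: float(v) for k, v in d["max"].items()}
        m.response_name_ = d.get("response_name")
        return m


# thin functional wrappers mirroring the fit/apply vocabulary


def fit_impute(train: Dataset) -> MeanModeImputer:
    return MeanModeImputer().fit(train)


def apply_impute(model: MeanModeImputer, data: Dataset) -> Dataset:
    return model.transform(data)


def fit_scale(train: Dataset, scale_response: bool = False) -> SymmetricScaler:
    return SymmetricScaler(scale_response=scale_response).fit(train)


def apply_scale(model: SymmetricScaler, data: Dataset) -> Dataset:
    return model.transform(data)
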