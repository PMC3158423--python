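import numpy as np
import pandas as pd
import pytest

from qsarkit.data import (
    CONTINUOUS,
    ENUMERATED,
    FEATURE,
    META,
    RESPONSE,
    Dataset,
    VariableSchema,
)
from qsarkit.learners import BaseLearner
from qsarkit.synth import SyntheticSpec, generate


@pytest.fixture
def clf_data():
    """Separable-ish 2-class dataset, 3 informative + 4 noise features."""
    data, _ = generate(
        SyntheticSpec(n_examples=150, n_informative=3, n_noise=4, sigma=0.2, seed=11)
    )
    return data


@pytest.fixture
def reg_data():
    data, _ = generate(
        SyntheticSpec(
            n_examples=120, n_informative=4, n_noise=2, task="regression", sigma=0.1, seed=5
        )
    )
    return data


@pytest.fixture
def separable_60():
    """60 examples, linearly separable by construction (noiseless latent)."""
    data, _ = generate(
        SyntheticSpec(n_examples=60, n_informative=2, n_noise=2, sigma=0.0, seed=3)
    )
    return data


def make_dataset(columns, n=None):
    """Build a Dataset from {name: (kind, role, values, levels)} shorthand."""
    schema, frame = [], {}
    for name, (kind, role, values, levels) in columns.items():
        schema.append(VariableSchema(name, kind, tuple(levels), role))
        frame[name] = values
    return Dataset(schema, pd.DataFrame(frame))


class LeakLearner(BaseLearner):
    """Perfect-oracle probe: predicts the class stored verbatim in the
    feature named ``leak`` (level codes). Exposes which rows it saw at fit
    time so leakage tests can assert train/test disjointness."""

    family = "leak"

    def __init__(self, random_state=0):
        self.random_state = random_state

    def _fit_core(self, X, y):
        self.leak_col_ = [v.name for v in self.schema_ if v.role == FEATURE].index("leak")
        self.seen_rows_ = {tuple(row) for row in np.round(X, 9)}

    def _proba_core(self, X):
        codes = np.clip(np.round(X[:, self.leak_col_]).astype(int), 0, len(self.classes_) - 1)
        p = np.zeros((len(X), len(self.classes_)))
        p[np.arange(len(X)), codes] = 1.0
        return p
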