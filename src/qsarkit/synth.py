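"""Deterministic synthetic data with known signal structure.

Every part of the platform is testable offline against datasets whose
generating process is recorded: standard-normal descriptors, a response
built from a declared signal form on a known informative block (the rest is
pure noise), Gaussian or label-flip noise at a declared level, and missing
cells injected at a declared rate. The ground-truth record carries the
generating coefficients, so the Bayes-optimal accuracy of a classification
spec can be computed and used as an upper sanity bound for any learner.

Signal forms
------------
linear
    latent s = X[informative] @ beta; regression adds N(0, sigma^2) to s,
    classification thresholds the noisy latent at quantiles of its
    theoretical N(0, ||beta||^2 + sigma^2) distribution chosen to hit the
    requested class balance.
xor
    two informative features; the class is the XOR of their signs, flipped
    with probability sigma. No linear classifier can beat chance by much,
    while interaction-capable learners can reach 1 - sigma.
radial
    the latent is the Euclidean norm of the informative block (classes cut
    at chi-distribution quantiles; regression predicts the norm plus noise).
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import Dataset
from .descriptors import LEXICAL_DESCRIPTORS


@dataclass
class SyntheticSpec:
    """Declarative recipe for one synthetic dataset."""

    n_examples: int = 200
    n_informative: int = 3
    n_noise: int = 5
    task: str = "classification"
    n_classes: int = 2
    balance: tuple[float, ...] | None = None  # None = uniform
    signal: str = "linear"  # linear | xor | radial
    sigma: float = 0.1
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_informative + self.n_noise < 1:
            raise ValueError("need at least one feature")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.task == "classification":
            if self.n_classes < 2:
                raise ValueError("classification needs >= 2 classes")
            if self.balance is not None:
                if len(self.balance) != self.n_classes or not np.isclose(
                    sum(self.balance), 1.0
                ):
                    raise ValueError("class balance must sum to 1, one weight per class")
        if self.signal == "xor" and (self.task != "classification" or self.n_informative != 2):
            raise ValueError("the xor signal needs classification with 2 informative features")


def _class_labels(k: int) -> tuple[str, ...]:
    return tuple(string.ascii_uppercase[:k])


def generate(spec: SyntheticSpec) -> tuple[Dataset, dict]:
    """Draw one dataset per the spec; fully determined by ``spec.seed``.

    Returns the dataset and a ground-truth record holding the informative
    indices, generating coefficients/thresholds and the noise level.
    """
    rng = np.random.default_rng(spec.seed)
    n, p_inf, p_noise = spec.n_examples, spec.n_informative, spec.n_noise
    p = p_inf + p_noise
    X = rng.standard_normal((n, p))
    inf_idx = list(range(p_inf))
    truth: dict = {
        "informative": inf_idx,
        "signal": spec.signal,
        "sigma": spec.sigma,
        "seed": spec.seed,
        "task": spec.task,
    }

    if spec.signal == "linear":
        beta = (rng.uniform(1.0, 2.0, size=p_inf)) * rng.choice([-1.0, 1.0], size=p_inf)
        truth["beta"] = beta.tolist()
        latent = X[:, :p_inf] @ beta if p_inf else np.zeros(n)
        noisy = latent + spec.sigma * rng.standard_normal(n)
        if spec.task == "regression":
            y = noisy
        else:
            scale = float(np.sqrt(beta @ beta + spec.sigma**2)) or 1.0
            balance = spec.balance or tuple([1.0 / spec.n_classes] * spec.n_classes)
            cuts = stats.norm.ppf(np.cumsum(balance)[:-1], scale=scale)
            truth["thresholds"] = cuts.tolist()
            y = np.digitize(noisy, cuts).astype(float)
    elif spec.signal == "xor":
        raw = np.logical_xor(X[:, 0] > 0, X[:, 1] > 0).astype(int)
        flips = rng.random(n) < spec.sigma
        y = np.where(flips, 1 - raw, raw).astype(float)
        truth["flip_probability"] = spec.sigma
        truth["bayes_accuracy"] = 1.0 - spec.sigma
    elif spec.signal == "radial":
        latent = np.linalg.norm(X[:, :p_inf], axis=1)
        if spec.task == "regression":
            y = latent + spec.sigma * rng.standard_normal(n)
        else:
            noisy = latent + spec.sigma * rng.standard_normal(n)
            balance = spec.balance or tuple([1.0 / spec.n_classes] * spec.n_classes)
            cuts = stats.chi.ppf(np.cumsum(balance)[:-1], df=max(p_inf, 1))
            truth["thresholds"] = cuts.tolist()
            y = np.digitize(noisy, cuts).astype(float)
    else:
        raise ValueError(f"unknown signal form {spec.signal!r}")

    if spec.missing_fraction > 0:
        mask = rng.random((n, p)) < spec.missing_fraction
        X = np.where(mask, np.nan, X)
        truth["n_missing_cells"] = int(mask.sum())

    if spec.task == "classification":
        labels = _class_labels(spec.n_classes)
        truth["class_labels"] = list(labels)
        data = Dataset.from_arrays(X, y, class_labels=labels)
    else:
        data = Dataset.from_arrays(X, y)
    return data, truth


def bayes_accuracy(truth: dict, n_mc: int = 200_000, seed: int = 1) -> float:
    """Monte-Carlo Bayes-optimal accuracy of a classification ground truth:
    the best any learner can do under the generating process."""
    if "bayes_accuracy" in truth:
        return float(truth["bayes_accuracy"])
    rng = np.random.default_rng(seed)
    if truth["signal"] == "linear":
        beta = np.asarray(truth["beta"])
        cuts = np.asarray(truth["thresholds"])
        s = rng.standard_normal((n_mc, len(beta))) @ beta
        noisy = s + truth["sigma"] * rng.standard_normal(n_mc)
        return float(np.mean(np.digitize(s, cuts) == np.digitize(noisy, cuts)))
    if truth["signal"] == "radial":
        k = len(truth["informative"])
        cuts = np.asarray(truth["thresholds"])
        s = stats.chi.rvs(df=k, size=n_mc, random_state=rng)
        noisy = s + truth["sigma"] * rng.standard_normal(n_mc)
        return float(np.mean(np.digitize(s, cuts) == np.digitize(noisy, cuts)))
    raise ValueError("no Bayes rule recorded for this ground truth")


# -- SMILES fixture generator -------------------------------------------------

_ELEMENTS = ["C", "C", "C", "C", "N", "O", "C", "S", "F", "Cl", "Br"]


def generate_smiles_fixture(n: int, seed: int = 0) -> tuple[list[str], list[dict]]:
    """Emit ``n`` syntactically valid simple SMILES (chains, one optional
    ring, branches, occasional double/triple bonds) with the generator's own
    token bookkeeping recorded per molecule, keyed like the builtin
    descriptor set."""
    rng = np.random.default_rng(seed)
    out_smiles: list[str] = []
    out_truth: list[dict] = []
    for _ in range(n):
        counts = dict.fromkeys(LEXICAL_DESCRIPTORS, 0.0)
        parts: list[str] = []

        def atom():
            el = _ELEMENTS[rng.integers(len(_ELEMENTS))]
            parts.append(el)
            counts["heavy_atoms"] += 1
            key = {
                "C": "carbon_count",
                "N": "nitrogen_count",
                "O": "oxygen_count",
                "S": "sulfur_count",
            }.get(el)
            if key:
                counts[key] += 1
            if el in ("F", "Cl", "Br"):
                counts["halogen_count"] += 1

        def maybe_bond():
            r = rng.random()
            if r < 0.12:
                parts.append("=")
                counts["double_bond_count"] += 1
            elif r < 0.16:
                parts.append("#")
                counts["triple_bond_count"] += 1

        use_ring = rng.random() < 0.4
        if use_ring:
            size = int(rng.integers(3, 7))
            atom()
            parts.append("1")
            for _ in range(size - 2):
                atom()
            atom()
            parts.append("1")
            counts["ring_count"] += 1
        else:
            length = int(rng.integers(2, 8))
            atom()
            for _ in range(length - 1):
                if rng.random() < 0.25:
                    parts.append("(")
                    counts["branch_count"] += 1
                    maybe_bond()
                    atom()
                    parts.append(")")
                maybe_bond()
                atom()
        smi = "".join(parts)
        counts["smiles_length"] = float(len(smi))
        out_smiles.append(smi)
        out_truth.append(counts)
    return out_smiles, out_truth


def write_smi(smiles: list[str], path) -> None:
    from pathlib import Path

    Path(path).write_text(
        "\n".join(f"{s}\tmol{i + 1}" for i, s in enumerate(smiles)) + "\n"
    )
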