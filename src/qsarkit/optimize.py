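"""Automated hyper-parameter selection by derivative-free pattern search.

The search operates on a mixed parameter space (continuous, integer and
enumerated axes; continuous axes may live on a log2 scale, in which case the
search moves in exponent space). It is a generating-set search: poll one
step up and down along every axis from the incumbent on the unit-normalized
space, accept the best improving poll point keeping the step, otherwise
halve the step, and stop when the step falls below a tolerance or the
evaluation budget is spent. Integer axes round polled points (round-half-down
on .5 ties), enumerated axes poll neighboring list positions, and duplicate
points after rounding are never re-evaluated.

The objective is a cross-validated score: classification accuracy
(maximized) or RMSE (minimized), with a fold assignment that depends only on
the dataset, fold count and seed — so every candidate parameter point is
scored on identical partitions. Before searching, the default parameter
configuration is always evaluated, and the search starts from the mid-point
of each parameter range (on its search scale) or, optionally, from the best
point of a sparse factorial grid.

Default search ranges per family: SVM C in [2^-5, 2^15] and gamma in
[2^-15, 2^3] (log2); boosted trees depth in [1, 20] and tree count in
[1, 1000]; PLS components in [1, nAttr-1]. The forest's active-attribute
count ([1, nAttr]) and the network's hidden-neuron count ([2, 30]) have no
published ranges; those two are this package's own defaults.
"""

from __future__ import annotations

import hashlib
import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml
from sklearn.model_selection import KFold, StratifiedKFold

from .data import Dataset
from .exceptions import InfeasibleFoldsError
from .learners import CLASSIFICATION, LearnerSpec, as_learner


def configure(spec, params: dict):
    """Overlay candidate hyper-parameters on a LearnerSpec or an estimator
    prototype, returning something ``as_learner`` can materialize."""
    if isinstance(spec, LearnerSpec):
        return LearnerSpec(spec.family, {**spec.params, **params})
    from sklearn.base import clone

    est = clone(spec)
    if params:
        est.set_params(**params)
    return est


def derive_seed(master: int, *tags) -> int:
    """Deterministic child seed from a master seed and a tag tuple (< 2^31)."""
    h = hashlib.blake2b(repr((int(master),) + tags).encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big") % (2**31 - 1)


def round_half_down(x: float) -> int:
    """Nearest integer, with .5 ties going down (10.5 -> 10)."""
    return int(math.ceil(x - 0.5))


# -- parameter spaces ---------------------------------------------------------


@dataclass(frozen=True)
class ParamSpec:
    """One tunable hyper-parameter: its type, bounds or value list, search
    scale and default."""

    name: str
    kind: str = "continuous"  # continuous | integer | enumerated
    lower: float | None = None
    upper: float | None = None
    values: tuple = ()
    scale: str = "linear"  # linear | log2
    default: object = None

    def __post_init__(self):
        if self.kind == "enumerated":
            if not self.values:
                raise ValueError(f"enumerated axis {self.name!r} needs values")
        else:
            if self.lower is None or self.upper is None or not self.lower < self.upper:
                raise ValueError(f"axis {self.name!r} needs lower < upper")
            if self.scale == "log2" and self.lower <= 0:
                raise ValueError(f"log2 axis {self.name!r} needs positive bounds")

    # unit-interval parameterization on the search scale

    def _lo_hi(self) -> tuple[float, float]:
        if self.scale == "log2":
            return math.log2(self.lower), math.log2(self.upper)
        return float(self.lower), float(self.upper)

    def from_unit(self, u: float):
        if self.kind == "enumerated":
            idx = int(np.clip(round_half_down(u * (len(self.values) - 1)), 0, len(self.values) - 1))
            return self.values[idx]
        lo, hi = self._lo_hi()
        v = lo + float(np.clip(u, 0.0, 1.0)) * (hi - lo)
        if self.scale == "log2":
            v = 2.0**v
        if self.kind == "integer":
            return int(np.clip(round_half_down(v), self.lower, self.upper))
        return v

    def to_unit(self, value) -> float:
        if self.kind == "enumerated":
            idx = self.values.index(value)
            return idx / max(len(self.values) - 1, 1)
        lo, hi = self._lo_hi()
        v = math.log2(value) if self.scale == "log2" else float(value)
        return (v - lo) / (hi - lo)

    def midpoint(self):
        """Mid-range value on the search scale (log2 axes: exponent midpoint)."""
        if self.kind == "enumerated":
            return self.values[round_half_down((len(self.values) - 1) / 2.0)]
        return self.from_unit(0.5)

    def grid_values(self, k: int) -> list:
        if self.kind == "enumerated":
            if k >= len(self.values):
                return list(self.values)
            us = np.linspace(0.0, 1.0, k) if k > 1 else [0.5]
            out = [self.from_unit(u) for u in us]
        else:
            us = np.linspace(0.0, 1.0, k) if k > 1 else [0.5]
            out = [self.from_unit(u) for u in us]
        return list(dict.fromkeys(out))

    @property
    def n_values(self) -> int | None:
        """Size of the discrete candidate set (None for continuous axes)."""
        if self.kind == "enumerated":
            return len(self.values)
        if self.kind == "integer":
            return int(self.upper) - int(self.lower) + 1
        return None


@dataclass
class ParamSpace:
    """Ordered hyper-parameter axes for one learner family."""

    family: str
    specs: list[ParamSpec] = field(default_factory=list)

    def __post_init__(self):
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names in space")

    def __iter__(self):
        return iter(self.specs)

    def __len__(self):
        return len(self.specs)

    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def defaults(self) -> dict:
        return {s.name: s.default for s in self.specs}

    def all_points(self) -> list[dict]:
        """Full enumeration of an all-discrete space."""
        grids = []
        for s in self.specs:
            if s.kind == "enumerated":
                grids.append(list(s.values))
            elif s.kind == "integer":
                grids.append(list(range(int(s.lower), int(s.upper) + 1)))
            else:
                raise ValueError("cannot enumerate a continuous axis")
        return [dict(zip(self.names(), combo)) for combo in itertools.product(*grids)]


def default_space(family: str, n_attr: int | None = None) -> ParamSpace:
    """The shipped per-family search space (see module docstring)."""
    if family == "svm":
        return ParamSpace(
            "svm",
            [
                ParamSpec("C", "continuous", 2.0**-5, 2.0**15, scale="log2", default=1.0),
                ParamSpec("gamma", "continuous", 2.0**-15, 2.0**3, scale="log2", default=2.0**-5),
            ],
        )
    if family == "boost":
        return ParamSpace(
            "boost",
            [
                ParamSpec("max_depth", "integer", 1, 20, default=3),
                ParamSpec("n_trees", "integer", 1, 1000, default=50),
            ],
        )
    if family == "pls":
        if n_attr is None or n_attr < 2:
            raise ValueError("PLS space needs the attribute count (nAttr >= 2)")
        return ParamSpace(
            "pls",
            [ParamSpec("n_components", "integer", 1, n_attr - 1, default=min(2, n_attr - 1))],
        )
    if family == "rf":
        if n_attr is None:
            raise ValueError("forest space needs the attribute count")
        return ParamSpace(
            "rf",
            [
                ParamSpec(
                    "mtry", "integer", 1, max(n_attr, 2),
                    default=max(1, round(math.sqrt(n_attr))),
                )
            ],
        )
    if family == "ann":
        return ParamSpace("ann", [ParamSpec("n_hidden", "integer", 2, 30, default=10)])
    raise ValueError(f"no default space for family {family!r}")


def load_space(path: str | Path) -> ParamSpace:
    """Read a declarative space config (YAML: family + one entry per axis
    with name, kind, bounds/values, scale, default)."""
    doc = yaml.safe_load(Path(path).read_text())
    specs = [
        ParamSpec(
            p["name"],
            p.get("kind", "continuous"),
            p.get("lower"),
            p.get("upper"),
            tuple(p.get("values", ())),
            p.get("scale", "linear"),
            p.get("default"),
        )
        for p in doc["params"]
    ]
    return ParamSpace(doc["family"], specs)


# -- CV objective -------------------------------------------------------------


def cv_folds(dataset: Dataset, folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic fold assignment from (dataset, folds, seed) alone:
    stratified for classification, shuffled k-fold for regression."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = dataset.y().to_numpy()
    if dataset.task == CLASSIFICATION:
        counts = np.bincount(y.astype(int))
        rare = counts[counts > 0].min() if counts.any() else 0
        if rare < folds:
            raise InfeasibleFoldsError(
                f"smallest class has {rare} member(s), fewer than {folds} folds"
            )
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in splitter.split(np.zeros(len(y)), y.astype(int))]
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros(len(y)))]


def cv_objective(
    spec,
    dataset: Dataset,
    folds: int = 5,
    seed: int = 0,
    repeats: int = 1,
) -> tuple[float, list[float]]:
    """Cross-validated objective for one candidate configuration: mean
    held-out accuracy (classification) or RMSE (regression) over the folds.
    The full pipeline — imputation, scaling, fitting — is refit on each
    training portion."""
    classification = dataset.task == CLASSIFICATION
    per_fold: list[float] = []
    for rep in range(repeats):
        fold_seed = seed if repeats == 1 else derive_seed(seed, "repeat", rep)
        for i, (tr, te) in enumerate(cv_folds(dataset, folds, fold_seed)):
            model = as_learner(spec, derive_seed(seed, "fold-train", rep, i))
            model.fit(dataset.subset(tr))
            test = dataset.subset(te)
            pred = model.predict(test)
            if classification:
                actual = test.response_labels().to_numpy()
                per_fold.append(float(np.mean(pred == actual)))
            else:
                actual = test.y().to_numpy()
                per_fold.append(float(np.sqrt(np.mean((pred - actual) ** 2))))
    return float(np.mean(per_fold)), per_fold


# -- pattern search -----------------------------------------------------------


@dataclass
class Evaluation:
    """One objective evaluation in the log."""

    params: dict
    value: float | None  # None marks an infeasible point
    per_fold: list[float] = field(default_factory=list)
    source: str = "search"


@dataclass
class OptimizationResult:
    """Search outcome: the winning parameters, their objective, and the full
    evaluation log in timestamp order (the default-configuration evaluation
    is always the first entry)."""

    best_params: dict
    best_value: float
    best_per_fold: list[float]
    log: list[Evaluation]
    maximize: bool
    init_source: str = "midpoint"
    family: str | None = None
    base_params: dict = field(default_factory=dict)

    def best_spec(self) -> LearnerSpec:
        """The learner spec with optimized rather than default parameters."""
        return LearnerSpec(self.family, {**self.base_params, **self.best_params})


def _better(a: float, b: float, maximize: bool) -> bool:
    return a > b if maximize else a < b


def select_best(
    log: Sequence[Evaluation], maximize: bool, variance_gate: bool = False
) -> Evaluation:
    """Scan the log in order and keep the running winner.

    With the variance gate on, a candidate replaces the incumbent only when
    its improvement exceeds the standard deviation of the incumbent's
    per-fold objective values — improvements smaller than the data-sampling
    noise are disregarded.
    """
    entries = [e for e in log if e.value is not None]
    if not entries:
        raise RuntimeError("every evaluated point was infeasible")
    incumbent = entries[0]
    for e in entries[1:]:
        if variance_gate:
            sd = float(np.std(incumbent.per_fold)) if incumbent.per_fold else 0.0
            gain = (e.value - incumbent.value) if maximize else (incumbent.value - e.value)
            if gain > sd:
                incumbent = e
        elif _better(e.value, incumbent.value, maximize):
            incumbent = e
    return incumbent


def midpoint_init(space: ParamSpace) -> dict:
    """Mid-range point of every axis, on each axis's search scale."""
    return {s.name: s.midpoint() for s in space}


class _Cache:
    def __init__(self, objective, log, max_evals):
        self.objective = objective
        self.log = log
        self.max_evals = max_evals
        self.seen: dict[tuple, Evaluation] = {}
        self.n_evals = 0

    def key(self, params: dict) -> tuple:
        return tuple(params[k] for k in sorted(params))

    def exhausted(self) -> bool:
        return self.n_evals >= self.max_evals

    def eval(self, params: dict, source: str) -> Evaluation | None:
        k = self.key(params)
        if k in self.seen:
            return self.seen[k]
        if self.exhausted():
            return None
        self.n_evals += 1
        try:
            out = self.objective(params)
        except Exception as exc:  # point infeasible; search continues
            entry = Evaluation(dict(params), None, [], f"{source}:infeasible:{exc}")
            self.log.append(entry)
            self.seen[k] = entry
            return entry
        value, per_fold = out if isinstance(out, tuple) else (out, [])
        entry = Evaluation(dict(params), float(value), list(per_fold), source)
        self.log.append(entry)
        self.seen[k] = entry
        return entry


def grid_init(
    space: ParamSpace,
    objective: Callable[[dict], object],
    points_per_axis: int | Sequence[int] = 3,
    maximize: bool = True,
    _cache: _Cache | None = None,
) -> dict:
    """Evaluate a full factorial sparse grid and return the best point."""
    if isinstance(points_per_axis, int):
        ppa = [points_per_axis] * len(space)
    else:
        ppa = list(points_per_axis)
    grids = [s.grid_values(k) for s, k in zip(space, ppa)]
    cache = _cache or _Cache(objective, [], math.inf)
    best_entry = None
    for combo in itertools.product(*grids):
        params = dict(zip(space.names(), combo))
        entry = cache.eval(params, "grid")
        if entry is None or entry.value is None:
            continue
        if best_entry is None or _better(entry.value, best_entry.value, maximize):
            best_entry = entry
    if best_entry is None:
        return midpoint_init(space)
    return dict(best_entry.params)


def pattern_search(
    space: ParamSpace,
    objective: Callable[[dict], object],
    init: dict | None = None,
    step0: float = 0.25,
    tol: float = 1.0 / 64,
    max_evals: int = 200,
    maximize: bool = True,
    _cache: _Cache | None = None,
) -> OptimizationResult:
    """Generating-set search over the unit-normalized space (see module
    docstring for the poll/step/stopping rules)."""
    log: list[Evaluation] = []
    cache = _cache if _cache is not None else _Cache(objective, log, max_evals)
    if _cache is not None:
        log = cache.log
    if init is None:
        init = midpoint_init(space)

    u = np.array([s.to_unit(init[s.name]) for s in space])
    incumbent = cache.eval(init, "init")
    delta = step0

    def value_of(entry):
        if entry is None or entry.value is None:
            return -math.inf if maximize else math.inf
        return entry.value

    while delta >= tol and not cache.exhausted():
        best_poll = None
        best_u = None
        anchor = incumbent.params if incumbent is not None else init
        for i, spec in enumerate(space):
            if spec.kind == "enumerated":
                idx = spec.values.index(anchor[spec.name])
                steps = []
                if idx + 1 < len(spec.values):
                    steps.append(idx + 1)
                if idx - 1 >= 0:
                    steps.append(idx - 1)
                for j in steps:
                    uu = u.copy()
                    uu[i] = j / max(len(spec.values) - 1, 1)
                    params = {s.name: s.from_unit(uu[k]) for k, s in enumerate(space)}
                    params[spec.name] = spec.values[j]
                    entry = cache.eval(params, "poll")
                    if _better(value_of(entry), value_of(best_poll), maximize):
                        best_poll, best_u = entry, uu
            else:
                for sign in (+1.0, -1.0):
                    uu = u.copy()
                    uu[i] = float(np.clip(uu[i] + sign * delta, 0.0, 1.0))
                    params = {s.name: s.from_unit(uu[k]) for k, s in enumerate(space)}
                    if spec.kind == "integer" and params[spec.name] == anchor[spec.name]:
                        # rounding swallowed the step: move one lattice point
                        nudged = int(
                            np.clip(anchor[spec.name] + int(sign), spec.lower, spec.upper)
                        )
                        params[spec.name] = nudged
                        uu[i] = spec.to_unit(nudged)
                    entry = cache.eval(params, "poll")
                    if _better(value_of(entry), value_of(best_poll), maximize):
                        best_poll, best_u = entry, uu
        if best_poll is not None and _better(
            value_of(best_poll), value_of(incumbent), maximize
        ):
            incumbent, u = best_poll, best_u
        else:
            delta /= 2.0
    winner = select_best(log, maximize) if log else incumbent
    return OptimizationResult(
        dict(winner.params),
        winner.value,
        list(winner.per_fold),
        log,
        maximize,
    )


def optimize_objective(
    space: ParamSpace,
    objective: Callable[[dict], object],
    maximize: bool = True,
    use_grid: bool = False,
    grid_points: int | Sequence[int] = 3,
    step0: float = 0.25,
    tol: float = 1.0 / 64,
    max_evals: int = 200,
    variance_gate: bool = False,
) -> OptimizationResult:
    """The full selection protocol over an arbitrary objective: evaluate the
    default configuration first, warm-start from the mid-range point (or the
    winner of a sparse factorial grid), pattern-search, and return the best
    of {default, every searched point} under the acceptance rule."""
    log: list[Evaluation] = []
    cache = _Cache(objective, log, max_evals)
    cache.eval(space.defaults(), "default")

    if len(space) == 0:
        winner = select_best(log, maximize, variance_gate)
        return OptimizationResult(
            dict(winner.params), winner.value, list(winner.per_fold), log,
            maximize, "default",
        )
    if use_grid:
        init = grid_init(space, objective, grid_points, maximize, _cache=cache)
        init_source = "grid"
    else:
        init, init_source = midpoint_init(space), "midpoint"

    pattern_search(
        space, objective, init=init, step0=step0, tol=tol,
        max_evals=max_evals, maximize=maximize, _cache=cache,
    )
    winner = select_best(log, maximize, variance_gate)
    return OptimizationResult(
        dict(winner.params), winner.value, list(winner.per_fold), log,
        maximize, init_source,
    )


def optimize_learner(
    spec: LearnerSpec,
    space: ParamSpace | None = None,
    dataset: Dataset = None,
    folds: int = 5,
    use_grid: bool = False,
    grid_points: int | Sequence[int] = 3,
    seed: int = 0,
    step0: float = 0.25,
    tol: float = 1.0 / 64,
    max_evals: int = 200,
    variance_gate: bool = False,
    repeats: int = 1,
) -> OptimizationResult:
    """Tune one learner's hyper-parameters on a dataset.

    Evaluates the default configuration first, then pattern-searches from
    the mid-range point (or from the winner of a sparse factorial grid with
    ``use_grid``). Any number of parameters is handled simultaneously. The
    returned winner is the best of {default, every searched point} under the
    acceptance rule; the fold partition is identical for all points.
    """
    if space is None:
        space = default_space(getattr(spec, "family", None), dataset.n_attr)
    maximize = dataset.task == CLASSIFICATION
    cv_seed = derive_seed(seed, "cv")

    def objective(params: dict):
        candidate = configure(spec, params)
        return cv_objective(candidate, dataset, folds=folds, seed=cv_seed, repeats=repeats)

    result = optimize_objective(
        space, objective, maximize=maximize, use_grid=use_grid,
        grid_points=grid_points, step0=step0, tol=tol, max_evals=max_evals,
        variance_gate=variance_gate,
    )
    if isinstance(spec, LearnerSpec):
        result.family = spec.family
        result.base_params = dict(spec.params)
    return result
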