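"""Pattern search, parameter spaces and the cross-validated objective."""

import numpy as np
import pytest

from qsarkit.exceptions import InfeasibleFoldsError
from qsarkit.learners import LearnerSpec
from qsarkit.optimize import (
    Evaluation,
    ParamSpace,
    ParamSpec,
    cv_folds,
    cv_objective,
    default_space,
    grid_init,
    load_space,
    midpoint_init,
    optimize_learner,
    optimize_objective,
    pattern_search,
    round_half_down,
    select_best,
)
from qsarkit.synth import SyntheticSpec, generate

from conftest import make_dataset
from qsarkit.data import CONTINUOUS, ENUMERATED, FEATURE, RESPONSE


class TestParamSpec:
    def test_log2_midpoint_is_exponent_midpoint(self):
        c = ParamSpec("C", "continuous", 2.0**-5, 2.0**15, scale="log2", default=1.0)
        assert c.midpoint() == 2.0**5

    def test_integer_midpoint_rounds_half_down(self):
        depth = ParamSpec("d", "integer", 1, 20, default=3)
        assert depth.midpoint() == 10  # 10.5 rounds down

    def test_round_half_down(self):
        assert round_half_down(10.5) == 10
        assert round_half_down(10.6) == 11
        assert round_half_down(-0.5) == -1

    def test_unit_roundtrip(self):
        g = ParamSpec("g", "continuous", 2.0**-15, 2.0**3, scale="log2", default=1.0)
        for v in (2.0**-15, 1.0, 2.0**3):
            assert np.isclose(g.from_unit(g.to_unit(v)), v)

    def test_log2_requires_positive_bounds(self):
        with pytest.raises(ValueError):
            ParamSpec("x", "continuous", -1, 1, scale="log2")


class TestGridAndMidpoint:
    def test_grid_with_one_point_per_axis_is_midpoint(self):
        space = default_space("boost")
        got = grid_init(space, lambda p: (0.0, []), points_per_axis=1)
        assert got == midpoint_init(space)

    def test_midpoint_of_default_svm_space(self):
        mid = midpoint_init(default_space("svm"))
        assert mid["C"] == 2.0**5
        assert mid["gamma"] == 2.0**-6


class TestPatternSearch:
    def test_converges_on_quadratic(self):
        space = ParamSpace("toy", [ParamSpec("x", "continuous", 0.0, 1.0, default=0.5)])
        res = pattern_search(
            space,
            lambda p: ((p["x"] - 0.3) ** 2, []),
            init={"x": 0.5},
            tol=1e-3,
            max_evals=500,
            maximize=False,
        )
        assert abs(res.best_params["x"] - 0.3) <= 2e-3

    def test_optimal_init_on_convex_function_stays_put(self):
        space = ParamSpace("toy", [ParamSpec("x", "continuous", 0.0, 1.0, default=0.5)])
        res = pattern_search(
            space, lambda p: ((p["x"] - 0.5) ** 2, []), init={"x": 0.5},
            maximize=False, max_evals=200,
        )
        assert res.best_params["x"] == 0.5

    def test_unimodal_enumerated_axis_reaches_optimum(self):
        table = {"a": 1.0, "b": 3.0, "c": 4.0, "d": 2.0}
        space = ParamSpace(
            "toy", [ParamSpec("v", "enumerated", values=("a", "b", "c", "d"), default="a")]
        )
        res = pattern_search(
            space, lambda p: (table[p["v"]], []), init={"v": "a"}, maximize=True
        )
        assert res.best_params["v"] == "c"

    def test_grid_warm_start_matches_brute_force_on_small_discrete_spaces(self):
        rng = np.random.default_rng(5)
        for trial in range(8):
            n1, n2 = rng.integers(2, 8), rng.integers(2, 8)
            space = ParamSpace(
                "toy",
                [
                    ParamSpec("i", "integer", 1, int(n1), default=1),
                    ParamSpec(
                        "e", "enumerated",
                        values=tuple(f"v{j}" for j in range(n2)), default="v0",
                    ),
                ],
            )
            table = {
                (p["e"], p["i"]): float(rng.random()) for p in space.all_points()
            }
            res = optimize_objective(
                space,
                lambda p: (table[(p["e"], p["i"])], []),
                maximize=True,
                use_grid=True,
                grid_points=[int(n1), int(n2)],
                max_evals=10_000,
            )
            assert res.best_value == max(table.values())

    def test_infeasible_points_are_recorded_and_search_continues(self):
        space = ParamSpace("toy", [ParamSpec("x", "continuous", 0.0, 1.0, default=0.5)])

        def objective(p):
            if p["x"] < 0.4:
                raise RuntimeError("boom")
            return ((p["x"] - 0.6) ** 2, [])

        res = pattern_search(space, objective, init={"x": 0.5}, maximize=False, max_evals=300)
        assert abs(res.best_params["x"] - 0.6) <= 0.05
        assert any("infeasible" in e.source for e in res.log)

    def test_duplicate_points_not_reevaluated(self):
        calls = []
        space = ParamSpace("toy", [ParamSpec("i", "integer", 1, 3, default=2)])

        def objective(p):
            calls.append(p["i"])
            return (float(p["i"]), [])

        pattern_search(space, objective, init={"i": 2}, maximize=True, max_evals=100)
        assert len(calls) == len(set(calls))


class TestSelectBest:
    def _log(self, values, per_fold=None):
        return [
            Evaluation({"i": k}, v, per_fold or [], "x") for k, v in enumerate(values)
        ]

    def test_plain_rule_takes_optimum(self):
        assert select_best(self._log([0.5, 0.9, 0.7]), maximize=True).value == 0.9

    def test_variance_gate_disregards_small_improvements(self):
        log = [
            Evaluation({"i": 0}, 0.80, [0.7, 0.8, 0.9], "default"),  # sd ~0.0816
            Evaluation({"i": 1}, 0.84, [0.84] * 3, "poll"),  # gain 0.04 < sd
            Evaluation({"i": 2}, 0.95, [0.95] * 3, "poll"),  # gain 0.15 > sd
        ]
        assert select_best(log, True, variance_gate=True).params["i"] == 2
        assert select_best(log[:2], True, variance_gate=True).params["i"] == 0


class TestCVObjective:
    def test_majority_dummy_accuracy_is_exact_class_prior(self):
        y = np.array([0.0] * 80 + [1.0] * 20)
        X = np.random.default_rng(0).standard_normal((100, 2))
        data = make_dataset(
            {
                "x0": (CONTINUOUS, FEATURE, X[:, 0], ()),
                "x1": (CONTINUOUS, FEATURE, X[:, 1], ()),
                "cls": (ENUMERATED, RESPONSE, y, ("A", "B")),
            }
        )
        value, per_fold = cv_objective(LearnerSpec("majority"), data, folds=5, seed=0)
        assert value == 0.80
        assert per_fold == [0.80] * 5  # each stratified fold holds 16A/4B

    def test_same_seed_reproduces_per_fold_values(self, clf_data):
        spec = LearnerSpec("rf", {"n_trees": 15})
        _, f1 = cv_objective(spec, clf_data, folds=5, seed=3)
        _, f2 = cv_objective(spec, clf_data, folds=5, seed=3)
        assert f1 == f2

    def test_fold_assignment_independent_of_candidate(self, clf_data):
        folds_a = cv_folds(clf_data, 5, seed=9)
        folds_b = cv_folds(clf_data, 5, seed=9)
        for (tra, tea), (trb, teb) in zip(folds_a, folds_b):
            assert np.array_equal(tea, teb)

    def test_rare_class_infeasible(self):
        data = make_dataset(
            {
                "x": (CONTINUOUS, FEATURE, [0.0, 1.0, 2.0, 3.0], ()),
                "cls": (ENUMERATED, RESPONSE, [0, 0, 0, 1], ("A", "B")),
            }
        )
        with pytest.raises(InfeasibleFoldsError):
            cv_objective(LearnerSpec("majority"), data, folds=3, seed=0)


class TestOptimizeLearner:
    @pytest.fixture()
    def data(self):
        d, _ = generate(
            SyntheticSpec(n_examples=120, n_informative=2, n_noise=3, sigma=0.3, seed=21)
        )
        return d

    def test_best_never_worse_than_default(self, data):
        res = optimize_learner(
            LearnerSpec("rf", {"n_trees": 20}),
            default_space("rf", data.n_attr),
            data,
            folds=3,
            seed=1,
            max_evals=8,
        )
        default_entry = res.log[0]
        assert default_entry.source == "default"
        assert res.best_value >= default_entry.value

    def test_component_polls_respect_nattr_bound(self):
        rdata, _ = generate(
            SyntheticSpec(
                n_examples=80, n_informative=3, n_noise=2, task="regression", sigma=0.2, seed=2
            )
        )
        res = optimize_learner(
            LearnerSpec("pls"), None, rdata, folds=3, seed=0, max_evals=20
        )
        polled = [e.params["n_components"] for e in res.log]
        assert all(1 <= c <= rdata.n_attr - 1 for c in polled)

    def test_identical_seeds_give_identical_logs(self, data):
        kw = dict(space=default_space("rf", data.n_attr), dataset=data, folds=3, seed=5, max_evals=6)
        r1 = optimize_learner(LearnerSpec("rf", {"n_trees": 15}), **kw)
        r2 = optimize_learner(LearnerSpec("rf", {"n_trees": 15}), **kw)
        assert [(e.params, e.value) for e in r1.log] == [(e.params, e.value) for e in r2.log]

    def test_result_emits_optimized_spec(self, data):
        res = optimize_learner(
            LearnerSpec("rf", {"n_trees": 20}),
            default_space("rf", data.n_attr),
            data,
            folds=3,
            seed=1,
            max_evals=6,
        )
        spec = res.best_spec()
        assert spec.family == "rf"
        assert spec.params["n_trees"] == 20  # base params preserved
        assert "mtry" in spec.params


def test_table_defaults_load_from_yaml(tmp_path):
    cfg = tmp_path / "space.yaml"
    cfg.write_text(
        """
family: svm
params:
  - {name: C, kind: continuous, lower: 0.03125, upper: 32768.0, scale: log2, default: 1.0}
  - {name: gamma, kind: continuous, lower: 0.000030517578125, upper: 8.0, scale: log2, default: 0.03125}
"""
    )
    space = load_space(cfg)
    assert space.names() == ["C", "gamma"]
    assert space.specs[0].midpoint() == 2.0**5
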