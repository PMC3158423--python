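"""Metric definitions, k-fold CV, the double CV loop and external tests."""

import numpy as np
import pytest

from qsarkit.data import CONTINUOUS, ENUMERATED, FEATURE, RESPONSE
from qsarkit.exceptions import NoDataError, NoResponseError
from qsarkit.learners import LearnerSpec, train
from qsarkit.optimize import ParamSpace, cv_folds
from qsarkit.validate import double_cv, evaluate_external, kfold_cv, metrics

from conftest import LeakLearner, make_dataset


class TestMetrics:
    def test_exact_predictions_have_zero_rmse(self):
        out = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "regression")
        assert out["rmse"] == 0.0

    def test_accuracy_counts_matches(self):
        out = metrics([0, 0, 0, 0], [0, 0, 0, 1], "classification")
        assert out["accuracy"] == 0.75

    def test_constant_actual_flags_undefined_q2(self):
        out = metrics([2.0, 2.0, 2.0], [2.0, 2.1, 1.9], "regression")
        assert out["q2"] is None and out["r2"] is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            metrics([1], [1, 2], "regression")


def leak_dataset(n=100, seed=0, leak_is_response=True):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n).astype(float)
    leak = y if leak_is_response else rng.integers(0, 2, n).astype(float)
    return make_dataset(
        {
            "leak": (CONTINUOUS, FEATURE, leak.astype(float), ()),
            "x": (CONTINUOUS, FEATURE, rng.normal(size=n), ()),
            "cls": (ENUMERATED, RESPONSE, y, ("A", "B")),
        }
    )


class TestKFold:
    def test_perfect_oracle_scores_one_with_diagonal_confusion(self):
        data = leak_dataset()
        res = kfold_cv(LeakLearner(), data, folds=5, seed=0)
        assert res.pooled_metrics["accuracy"] == 1.0
        assert np.all(res.confusion.counts == np.diag(np.diag(res.confusion.counts)))

    def test_majority_dummy_on_imbalanced_data(self):
        y = np.array([0.0] * 80 + [1.0] * 20)
        data = make_dataset(
            {
                "x": (CONTINUOUS, FEATURE, np.arange(100, dtype=float), ()),
                "cls": (ENUMERATED, RESPONSE, y, ("A", "B")),
            }
        )
        res = kfold_cv(LearnerSpec("majority"), data, folds=5, seed=0)
        assert res.pooled_metrics["accuracy"] == 0.80

    def test_every_example_predicted_exactly_once(self, clf_data):
        res = kfold_cv(LearnerSpec("rf", {"n_trees": 10}), clf_data, folds=5, seed=1)
        assert (res.fold_of_example >= 0).all()
        assert res.confusion.counts.sum() == len(clf_data)

    def test_mean_dummy_regression_has_nonpositive_q2(self, reg_data):
        res = kfold_cv(LearnerSpec("majority"), reg_data, folds=5, seed=0)
        assert res.pooled_metrics["q2"] <= 1e-12
        for fold in res.per_fold_metrics:
            assert fold["q2"] <= 1e-9

    def test_pooled_accuracy_is_count_weighted_fold_mean(self, clf_data):
        res = kfold_cv(LearnerSpec("rf", {"n_trees": 15}), clf_data, folds=5, seed=2)
        sizes = np.bincount(res.fold_of_example)
        weighted = sum(
            m["accuracy"] * s for m, s in zip(res.per_fold_metrics, sizes)
        ) / len(clf_data)
        assert np.isclose(res.pooled_metrics["accuracy"], weighted)


class TestDoubleCV:
    def test_outer_folds_partition_dataset(self, clf_data):
        res = double_cv(
            LearnerSpec("majority"),
            ParamSpace("majority", []),
            clf_data,
            outer_folds=4,
            inner_folds=3,
            seed=3,
        )
        assert sorted(np.unique(res.fold_of_example)) == [0, 1, 2, 3]
        assert (np.bincount(res.fold_of_example) > 0).all()

    def test_empty_space_degenerates_to_kfold(self, clf_data):
        plain = kfold_cv(LearnerSpec("majority"), clf_data, folds=5, seed=7)
        nested = double_cv(
            LearnerSpec("majority"),
            ParamSpace("majority", []),
            clf_data,
            outer_folds=5,
            inner_folds=3,
            seed=7,
        )
        assert nested.pooled_metrics == plain.pooled_metrics

    def test_never_trains_on_the_held_out_fold(self):
        """Instrumented learner records every row it is fitted on; inside
        double CV no fit (inner-CV or final) may touch its outer test fold."""
        data = leak_dataset(80, seed=4)
        outer, inner = 4, 3
        folds = cv_folds(data, outer, 11)
        seen_sets = []

        class RecordingLeak(LeakLearner):
            def _fit_core(self, X, y):
                super()._fit_core(X, y)
                seen_sets.append(self.seen_rows_)

        double_cv(
            RecordingLeak(), ParamSpace("leak", []), data,
            outer_folds=outer, inner_folds=inner, seed=11,
        )
        # per outer fold: `inner` fits for the default evaluation + 1 final fit
        fits_per_fold = inner + 1
        assert len(seen_sets) == outer * fits_per_fold
        X_all = np.round(
            np.c_[data.df["leak"].to_numpy(), data.df["x"].to_numpy()], 9
        )
        for i, (tr, te) in enumerate(folds):
            held_out_rows = {tuple(row) for row in X_all[te]}
            for seen in seen_sets[i * fits_per_fold : (i + 1) * fits_per_fold]:
                assert not (held_out_rows & seen)

    def test_leak_feature_detected_then_noise_restores_chance(self):
        informative = leak_dataset(120, seed=5, leak_is_response=True)
        res = double_cv(
            LearnerSpec("rf", {"n_trees": 20}),
            ParamSpace("rf", []),
            informative,
            outer_folds=4,
            inner_folds=3,
            seed=1,
        )
        assert res.pooled_metrics["accuracy"] >= 0.95

        nulled = leak_dataset(120, seed=5, leak_is_response=False)
        res0 = double_cv(
            LearnerSpec("rf", {"n_trees": 20}),
            ParamSpace("rf", []),
            nulled,
            outer_folds=4,
            inner_folds=3,
            seed=1,
        )
        # 99% binomial band around 0.5 at n=120
        band = 2.576 * np.sqrt(0.25 / 120)
        assert abs(res0.pooled_metrics["accuracy"] - 0.5) <= band + 1e-9

    def test_per_fold_parameters_recorded(self, clf_data):
        from qsarkit.optimize import default_space

        res = double_cv(
            LearnerSpec("rf", {"n_trees": 15}),
            default_space("rf", clf_data.n_attr),
            clf_data,
            outer_folds=3,
            inner_folds=3,
            seed=2,
            max_evals=5,
        )
        assert len(res.fold_params) == 3
        assert all("mtry" in p for p in res.fold_params)


class TestExternal:
    def test_direct_count_example(self):
        actual = ["A", "B", "B", "B"]
        predicted = ["A", "A", "B", "B"]
        out = metrics(np.array(actual), np.array(predicted), "classification")
        assert out["accuracy"] == 0.75
        from qsarkit.validate import ConfusionMatrix

        cm = ConfusionMatrix.from_predictions(actual, predicted, ("A", "B"))
        assert cm.counts.tolist() == [[1, 0], [1, 2]]

    def test_memorizing_model_scores_one_on_training_data(self):
        data = leak_dataset(60, seed=6)
        model = train(LeakLearner(), data, seed=0)
        out = evaluate_external(model, data)
        assert out["accuracy"] == 1.0

    def test_empty_test_set_rejected(self, clf_data):
        model = train(LearnerSpec("majority"), clf_data, seed=0)
        with pytest.raises(NoDataError):
            evaluate_external(model, clf_data.subset([]))

    def test_missing_response_rejected(self, clf_data):
        model = train(LearnerSpec("majority"), clf_data, seed=0)
        with pytest.raises(NoResponseError):
            evaluate_external(model, clf_data.drop_response())
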