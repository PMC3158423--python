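"""Out-of-bag permutation importance and top-k selection."""

import numpy as np
import pytest

import qsarkit.importance as imp_mod
from qsarkit.data import CONTINUOUS, ENUMERATED, FEATURE, RESPONSE
from qsarkit.exceptions import UnsupportedModelError
from qsarkit.importance import oob_importance, rank_then_select
from qsarkit.learners import LearnerSpec, train
from qsarkit.synth import SyntheticSpec, generate

from conftest import make_dataset


def label_copy_dataset(n=150, n_noise=5, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n).astype(float)
    cols = {"copy": (CONTINUOUS, FEATURE, y + 0.0, ())}
    for j in range(n_noise):
        cols[f"n{j}"] = (CONTINUOUS, FEATURE, rng.normal(size=n), ())
    cols["cls"] = (ENUMERATED, RESPONSE, y, ("A", "B"))
    return make_dataset(cols)


class TestOOBImportance:
    def test_label_copy_feature_ranks_first(self):
        data = label_copy_dataset()
        rf = train(LearnerSpec("rf", {"n_trees": 100}), data, seed=1)
        result = oob_importance(rf, data, seed=0)
        assert result.features[np.argmin(result.ranks)] == "copy"
        assert result.ranks[result.features.index("copy")] == 1

    def test_single_feature_dataset_ranks_it_first(self):
        data = label_copy_dataset(n_noise=0)
        rf = train(LearnerSpec("rf", {"n_trees": 30}), data, seed=0)
        result = oob_importance(rf, data, seed=0)
        assert list(result.ranks) == [1]

    def test_ranks_are_a_permutation(self, clf_data):
        rf = train(LearnerSpec("rf", {"n_trees": 40}), clf_data, seed=2)
        result = oob_importance(rf, clf_data, seed=3)
        assert sorted(result.ranks) == list(range(1, clf_data.n_attr + 1))

    def test_seeded_permutations_reproducible(self, clf_data):
        rf = train(LearnerSpec("rf", {"n_trees": 40}), clf_data, seed=2)
        r1 = oob_importance(rf, clf_data, seed=5)
        r2 = oob_importance(rf, clf_data, seed=5)
        assert np.array_equal(r1.importances, r2.importances)

    def test_non_forest_model_rejected(self, clf_data):
        svm = train(LearnerSpec("svm"), clf_data, seed=0)
        with pytest.raises(UnsupportedModelError):
            oob_importance(svm, clf_data, seed=0)

    def test_permutation_confined_to_oob_rows(self, monkeypatch, clf_data):
        """Every matrix scored during importance holds exactly the tree's OOB
        rows, and the permuted copy differs from the baseline in one column
        only — in-bag cells are never touched."""
        rf = train(LearnerSpec("rf", {"n_trees": 10}), clf_data, seed=4)
        calls = []
        original = imp_mod._fast_predict

        def spy(tree, X32, classification):
            calls.append(np.array(X32))
            return original(tree, X32, classification)

        monkeypatch.setattr(imp_mod, "_fast_predict", spy)
        oob_importance(rf, clf_data, seed=0)

        n_feats = clf_data.n_attr
        per_tree = n_feats + 1  # baseline + one permutation per feature
        forest = rf.model_
        X = rf._encoded(clf_data).astype(np.float32)
        tree_calls = [calls[i * per_tree : (i + 1) * per_tree] for i in range(10)]
        for in_bag, group in zip(forest.estimators_samples_, tree_calls):
            oob = np.ones(len(X), dtype=bool)
            oob[in_bag] = False
            baseline = group[0]
            assert np.array_equal(baseline, X[oob])
            for j, permuted in enumerate(group[1:]):
                other = np.delete(permuted, j, axis=1)
                other_base = np.delete(baseline, j, axis=1)
                assert np.array_equal(other, other_base)  # only column j moved
                assert sorted(permuted[:, j]) == sorted(baseline[:, j])

    def test_duplicated_informative_feature_shares_credit(self):
        """Adding an exact copy of the informative feature lowers its
        permutation importance (directional, across seeds)."""
        drops = 0
        for seed in range(3):
            data, _ = generate(
                SyntheticSpec(n_examples=250, n_informative=1, n_noise=4, sigma=0.1, seed=seed)
            )
            rf = train(LearnerSpec("rf", {"n_trees": 150}), data, seed=seed)
            solo = oob_importance(rf, data, seed=seed).importances[0]

            dup = data.df.copy()
            dup["x0_copy"] = dup["x0"]
            from qsarkit.data import Dataset, VariableSchema

            wide = Dataset(
                list(data.schema) + [VariableSchema("x0_copy")],
                dup,
            )
            rf2 = train(LearnerSpec("rf", {"n_trees": 150}), wide, seed=seed)
            shared = oob_importance(rf2, wide, seed=seed).importances[0]
            drops += shared < solo
        assert drops >= 2


class TestRankThenSelect:
    def test_keep_all_is_identity(self, clf_data):
        out = rank_then_select(clf_data, np.arange(clf_data.n_attr, dtype=float), clf_data.n_attr)
        assert out.feature_names == clf_data.feature_names

    def test_fraction_keeps_half(self):
        data, _ = generate(SyntheticSpec(n_examples=50, n_informative=2, n_noise=8, seed=0))
        out = rank_then_select(data, np.arange(10, dtype=float), 0.5)
        assert out.n_attr == 5

    def test_overshoot_clipped_with_warning(self, clf_data):
        with pytest.warns(UserWarning, match="keeping all"):
            out = rank_then_select(clf_data, np.ones(clf_data.n_attr), clf_data.n_attr + 5)
        assert out.n_attr == clf_data.n_attr

    def test_top_scores_win(self, clf_data):
        scores = np.zeros(clf_data.n_attr)
        scores[1] = 2.0
        scores[3] = 1.0
        out = rank_then_select(clf_data, scores, 2)
        assert set(out.feature_names) == {clf_data.feature_names[1], clf_data.feature_names[3]}
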