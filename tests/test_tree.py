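"""CART engine: impurity arithmetic, split search, growth, CV depth tuning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from severitree.cohort import GeneratorConfig, generate_cohort
from severitree.tree import (CartClassifier, audit_tree, best_split, gini_impurity,
                             select_max_depth, split_gain)


class TestGini:
    @pytest.mark.parametrize("counts,expected", [
        ((10, 0, 0), 0.0),
        ((5, 5), 0.5),
        ((1, 2, 3), 11 / 18),
    ])
    def test_values(self, counts, expected):
        assert gini_impurity(counts) == pytest.approx(expected, abs=1e-15)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity([0, 0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 50), min_size=2, max_size=5).filter(lambda c: sum(c) > 0))
    def test_bounded_by_one_minus_inverse_k(self, counts):
        g = gini_impurity(counts)
        assert 0.0 <= g <= 1.0 - 1.0 / len(counts) + 1e-12


class TestSplitGain:
    def test_perfect_separation(self):
        assert split_gain((5, 5), (5, 0), (0, 5)) == pytest.approx(0.5)

    def test_empty_child_rejected(self):
        with pytest.raises(ValueError):
            split_gain((5, 5), (5, 5), (0, 0))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            split_gain((5, 5), (3, 1), (1, 3))

    def test_arithmetic_example(self):
        assert split_gain((4, 4), (3, 1), (1, 3)) == pytest.approx(0.125)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 20), st.integers(0, 20)),
                    min_size=2, max_size=4))
    def test_gain_nonnegative(self, pairs):
        left = np.array([l for l, _ in pairs])
        right = np.array([r for _, r in pairs])
        if left.sum() == 0 or right.sum() == 0:
            return
        assert split_gain(left + right, left, right) >= -1e-12


class TestBestSplit:
    def test_perfectly_ordered_predictor(self):
        X = pd.DataFrame({"x": [0, 0, 1, 1, 2, 2, 3, 3]})
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        cand = best_split(X, y)
        assert cand.threshold == 1.5
        assert cand.gain == pytest.approx(0.5)  # parent impurity: pure children

    def test_constant_predictor_returns_none(self):
        assert best_split(pd.DataFrame({"x": [1] * 10}), np.arange(10) % 2) is None

    def test_minbucket_blocks_unbalanced_split(self):
        X = pd.DataFrame({"x": [0] * 9 + [3]})
        y = np.array([0] * 9 + [1])
        assert best_split(X, y, minbucket=2) is None

    def test_nominal_partition(self):
        X = pd.DataFrame({"g": list("aabbcc")})
        y = np.array([0, 0, 1, 1, 0, 0])
        cand = best_split(X, y)
        assert cand.kind == "nominal"
        assert set(cand.left_categories) in ({"b"}, {"a", "c"})
        assert cand.gain == pytest.approx(gini_impurity([4, 2]))

    def test_matches_brute_force_on_random_tiny_nodes(self, rng):
        """Chosen gain equals exhaustive enumeration of every legal split."""
        for _ in range(30):
            n = int(rng.integers(5, 31))
            X = pd.DataFrame({f"x{j}": rng.integers(0, 4, n) for j in range(2)})
            y = rng.integers(0, 3, n)
            if len(np.unique(y)) < 2:
                continue
            cand = best_split(X, y, minbucket=1)
            best = 0.0
            parent = np.bincount(y, minlength=3)
            for col in X.columns:
                v = X[col].to_numpy()
                for t in np.unique(v)[:-1]:
                    left = np.bincount(y[v <= t], minlength=3)
                    best = max(best, split_gain(parent, left, parent - left))
            got = cand.gain if cand is not None else 0.0
            assert got == pytest.approx(best, abs=1e-12)


def _classes_from_total(X):
    total = X.sum(axis=1)
    return np.where(total >= 12, 2, np.where(total >= 6, 1, 0))


class TestGrowth:
    def test_pure_training_set_single_leaf(self):
        X = pd.DataFrame({"x": [0, 1, 2, 3] * 5})
        clf = CartClassifier(minsplit=2, minbucket=1).fit(X, np.zeros(20))
        assert clf.tree_.is_leaf
        audit_tree(clf)

    def test_stump_with_max_depth_one(self):
        X = pd.DataFrame({"x": [0, 0, 1, 1, 2, 2, 3, 3] * 3})
        y = (X["x"] >= 2).astype(int)
        clf = CartClassifier(minsplit=2, minbucket=1, max_depth=1).fit(X, y)
        assert not clf.tree_.is_leaf
        assert clf.tree_.left.is_leaf and clf.tree_.right.is_leaf
        audit_tree(clf)

    def test_structural_audit_on_synthetic_cohort(self):
        cohort = generate_cohort(GeneratorConfig(n=800, seed=5))
        X = cohort[["GAD1", "GAD2", "GAD3", "GAD4", "GAD5", "GAD6", "GAD7"]]
        clf = CartClassifier(minsplit=60, minbucket=25, max_depth=5).fit(
            X, cohort["severity"].to_numpy())
        audit_tree(clf)

    def test_empty_training_table_rejected(self):
        with pytest.raises(ValueError):
            CartClassifier().fit(pd.DataFrame({"x": []}), np.array([]))

    def test_scale_to_n_rescales_constraints(self):
        X = pd.DataFrame({"x": np.arange(1441) % 4})
        y = (X["x"] >= 2).astype(int)
        clf = CartClassifier(minsplit=500, minbucket=500, max_depth=2,
                             scale_to_n=True, reference_n=14410).fit(X, y)
        assert clf.minsplit_effective_ == 50
        assert clf.minbucket_effective_ == 50

    def test_adding_separating_predictor_never_lowers_root_gain(self, rng):
        """Monotone gain: a strictly separating extra predictor can only
        raise the best root gain."""
        for _ in range(10):
            n = 40
            X = pd.DataFrame({"x0": rng.integers(0, 4, n)})
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            base = best_split(X, y)
            base_gain = base.gain if base else 0.0
            X2 = X.assign(sep=y * 3)
            assert best_split(X2, y).gain >= base_gain - 1e-12


class TestDepthSelection:
    def test_perfect_predictor_selects_depth_one(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 4, 400)
        X = pd.DataFrame({"x": x, "noise": rng.integers(0, 4, 400)})
        y = (x >= 2).astype(int)
        clf = CartClassifier(minsplit=20, minbucket=7, random_state=0).fit(X, y)
        assert clf.max_depth_ == 1

    def test_pure_noise_outcome_selects_minimum_depth(self):
        """With (imbalanced) labels independent of the predictors, shallow
        trees keep the majority-class margin while deeper noise-chasing
        splits erode it, so CV picks the grid minimum in the large majority
        of replicates."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            X = pd.DataFrame({f"x{j}": rng.integers(0, 4, 400) for j in range(3)})
            y = (rng.random(400) < 0.2).astype(int)
            depth = select_max_depth(X, y, minsplit=30, minbucket=10,
                                     random_state=seed)
            hits += depth == 1
        assert hits >= 40

    def test_deterministic_given_seed(self):
        cohort = generate_cohort(GeneratorConfig(n=600, seed=8))
        X = cohort[[f"GAD{i}" for i in range(1, 8)]]
        y = cohort["severity"].to_numpy()
        d1 = select_max_depth(X, y, minsplit=50, minbucket=20, random_state=3)
        d2 = select_max_depth(X, y, minsplit=50, minbucket=20, random_state=3)
        assert d1 == d2

    def test_too_few_rows_for_folds_rejected(self):
        X = pd.DataFrame({"x": np.arange(5)})
        with pytest.raises(ValueError, match="cv"):
            CartClassifier(minsplit=2, minbucket=1, cv=10).fit(X, np.arange(5) % 2)


class TestPredict:
    def test_single_leaf_tree_predicts_majority(self):
        X = pd.DataFrame({"x": [0, 1, 2, 3]})
        clf = CartClassifier(minsplit=100, minbucket=1, max_depth=3).fit(
            X, np.array(["a", "a", "a", "b"]))
        assert clf.tree_.is_leaf
        assert list(clf.predict(X)) == ["a"] * 4

    def test_probabilities_sum_to_one(self, small_gad_cohort):
        X = small_gad_cohort[[f"GAD{i}" for i in range(1, 8)]]
        clf = CartClassifier(minsplit=100, minbucket=40, max_depth=4).fit(
            X, small_gad_cohort["severity"].to_numpy())
        proba = clf.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert proba.min() >= 0

    def test_threshold_value_routes_left(self):
        """A row sitting exactly on the split value k goes left of the k+0.5
        threshold (condition is value < k + 0.5)."""
        X = pd.DataFrame({"x": [0, 0, 0, 1, 1, 1]})
        y = np.array([0, 0, 0, 1, 1, 1])
        clf = CartClassifier(minsplit=2, minbucket=1, max_depth=2).fit(X, y)
        assert clf.tree_.split.threshold == 0.5
        assert clf.predict(pd.DataFrame({"x": [0]}))[0] == 0
        assert clf.predict(pd.DataFrame({"x": [1]}))[0] == 1

    def test_leaf_tie_breaks_to_more_severe_class(self):
        X = pd.DataFrame({"x": [0, 0, 1, 1]})
        y = np.array(["minimal_mild", "severe", "minimal_mild", "severe"])
        clf = CartClassifier(minsplit=100, minbucket=1, max_depth=2).fit(X, y)
        assert clf.tree_.is_leaf  # 2/2 tie at the root
        assert clf.predict(X.iloc[[0]])[0] == "severe"

    def test_missing_value_rejected(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0] * 3})
        clf = CartClassifier(minsplit=2, minbucket=1).fit(X, (X["x"] > 1).astype(int))
        with pytest.raises(ValueError, match="missing"):
            clf.predict(pd.DataFrame({"x": [np.nan]}))


class TestImportance:
    def test_stump_concentrates_importance(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"GAD2": rng.integers(0, 4, 100),
                          "GAD5": rng.integers(0, 4, 100)})
        y = (X["GAD2"] >= 2).astype(int)
        clf = CartClassifier(minsplit=2, minbucket=1, max_depth=1).fit(X, y)
        imp = clf.variable_importance()
        assert imp["GAD2"] > 0 and imp["GAD5"] == 0.0

    def test_single_leaf_importances_zero(self):
        X = pd.DataFrame({"x": [0, 1, 2, 3]})
        clf = CartClassifier(minsplit=2, minbucket=1, max_depth=2).fit(X, np.zeros(4))
        assert all(v == 0 for v in clf.variable_importance().values())

    def test_null_demographics_carry_negligible_importance(self):
        """With demographic_effect=0 the summed demographic importance stays
        under 5% of the total in nearly every seeded tree."""
        ok = 0
        for seed in range(50):
            cohort = generate_cohort(GeneratorConfig(n=1200, seed=500 + seed))
            cols = [f"GAD{i}" for i in range(1, 8)] + ["sex", "education"]
            clf = CartClassifier(minsplit=100, minbucket=40, max_depth=4,
                                 random_state=seed).fit(
                cohort[cols], cohort["severity"].to_numpy())
            imp = clf.variable_importance()
            total = sum(imp.values())
            demo = imp["sex"] + imp["education"]
            ok += total > 0 and demo < 0.05 * total
        assert ok >= 45


class TestSklearnCompat:
    def test_get_set_params_roundtrip(self):
        clf = CartClassifier(minsplit=10)
        params = clf.get_params()
        assert params["minsplit"] == 10
        clf.set_params(minbucket=3)
        assert clf.minbucket == 3

    def test_cross_val_score_integration(self):
        from sklearn.model_selection import cross_val_score
        cohort = generate_cohort(GeneratorConfig(n=600, seed=13))
        X = cohort[[f"GAD{i}" for i in range(1, 8)]]
        scores = cross_val_score(
            CartClassifier(minsplit=40, minbucket=15, max_depth=3),
            X, cohort["severity"].to_numpy(), cv=3)
        assert scores.shape == (3,) and (scores > 0.4).all()
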