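"""Boosted regression trees: split oracle, reference fit, AUC, projections."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import paleorange as pr
from paleorange.brt import (
    LEAF_CLIP,
    TreeNode,
    partial_dependence,
    pd_optimum,
    save_model,
    load_model,
)


def make_table(X, y, names=None):
    names = names or [f"v{j}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "label", y)
    return df


# --------------------------------------------------------------------------
# independent oracles

def brute_force_stump(X, r):
    """Exhaustive search over every (variable, midpoint) candidate for the
    split minimizing squared error of the residuals; ties to lowest variable,
    then lowest threshold."""
    best = None
    n = len(r)
    for j in range(X.shape[1]):
        values = np.unique(X[:, j])
        for a, b in zip(values[:-1], values[1:]):
            thr = (a + b) / 2
            left = X[:, j] < thr
            nl, nr_ = left.sum(), n - left.sum()
            sse = ((r[left] - r[left].mean()) ** 2).sum() + (
                (r[~left] - r[~left].mean()) ** 2
            ).sum()
            if best is None or sse < best[0] - 1e-12:
                best = (sse, j, thr)
    return best[1], best[2]


def reference_brt(X, y, lr, n_stages):
    """Hand-rolled stump boosting (bag fraction 1): plain loops, no shared code
    with the implementation under test."""
    p0 = y.mean()
    F = np.full(len(y), np.log(p0 / (1 - p0)))
    preds = []
    for _ in range(n_stages):
        p = 1 / (1 + np.exp(-F))
        r = y - p
        j, thr = brute_force_stump(X, r)
        left = X[:, j] < thr
        vl = r[left].sum() / max((p[left] * (1 - p[left])).sum(), 1e-12)
        vr = r[~left].sum() / max((p[~left] * (1 - p[~left])).sum(), 1e-12)
        vl, vr = np.clip(vl, -4, 4), np.clip(vr, -4, 4)
        F = F + lr * np.where(left, vl, vr)
    return F


# --------------------------------------------------------------------------

class TestFitBrt:
    def test_separable_data_first_stump_in_gap(self):
        x = np.concatenate([np.linspace(-2, -0.5, 10), np.linspace(0.5, 2, 10)])
        y = (x > 0).astype(float)
        table = make_table(x[:, None], y)
        model, report = pr.fit_brt(
            table, bag_fraction=1.0, max_trees=5, seed=0, test_fraction=0.2
        )
        stump = model.trees[0]
        assert -0.5 < stump.split < 0.5
        assert report.auc_train == 1.0

    def test_zero_learning_rate_is_intercept_model(self):
        rng = np.random.default_rng(0)
        X = rng.random((40, 3))
        y = rng.integers(0, 2, 40).astype(float)
        table = make_table(X, y)
        model, _ = pr.fit_brt(table, lr=0.0, max_trees=10, seed=1)
        p = model.predict_proba(X)
        train_prevalence = 1 / (1 + np.exp(-model.intercept))
        np.testing.assert_allclose(p, train_prevalence)

    def test_first_stump_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 4))
        y = (X[:, 2] + 0.3 * rng.standard_normal(30) > 0).astype(float)
        table = make_table(X, y)
        model, _ = pr.fit_brt(
            table, bag_fraction=1.0, max_trees=1, seed=0, test_fraction=0.0
        )
        r0 = y - y.mean()  # initial negative gradient
        j, thr = brute_force_stump(X, r0)
        stump = model.trees[0]
        assert stump.variable == j
        assert stump.split == pytest.approx(thr)

    def test_three_stage_fit_matches_reference_to_1e10(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((18, 3))
        y = (X[:, 0] - 0.5 * X[:, 1] > 0).astype(float)
        table = make_table(X, y)
        model, _ = pr.fit_brt(
            table, lr=0.1, bag_fraction=1.0, max_trees=3, seed=0, test_fraction=0.0
        )
        F_ref = reference_brt(X, y, 0.1, 3)
        model.n_trees_used = 3
        np.testing.assert_allclose(model.decision_function(X), F_ref, atol=1e-10)

    def test_reproducible_under_seed(self, cold_species_setup):
        *_, table = cold_species_setup
        m1, r1 = pr.fit_brt(table, max_trees=30, seed=42)
        m2, r2 = pr.fit_brt(table, max_trees=30, seed=42)
        assert r1.n_trees_used == r2.n_trees_used
        np.testing.assert_array_equal(
            r1.holdout_deviance_path, r2.holdout_deviance_path
        )
        X = m1.calibration_rows
        np.testing.assert_array_equal(m1.predict_proba(X), m2.predict_proba(X))

    def test_selected_stage_never_worse_than_null(self, cold_species_setup):
        *_, table = cold_species_setup
        _, report = pr.fit_brt(table, max_trees=50, seed=7)
        path = report.holdout_deviance_path
        assert path[report.n_trees_used] <= path[0]

    def test_train_deviance_nonincreasing_full_bag_small_lr(self, cold_species_setup):
        *_, table = cold_species_setup
        _, report = pr.fit_brt(
            table, lr=0.01, bag_fraction=1.0, max_trees=40, seed=1
        )
        diffs = np.diff(report.train_deviance_path)
        assert (diffs <= 1e-12).all()

    def test_single_class_rejected(self):
        table = make_table(np.random.rand(10, 2), np.ones(10))
        with pytest.raises(ValueError, match="presence"):
            pr.fit_brt(table, max_trees=5, seed=0)

    def test_stratified_split_preserves_balance(self, cold_species_setup):
        *_, table = cold_species_setup  # 80 + 80
        _, report = pr.fit_brt(table, max_trees=5, seed=3)
        assert report.split_fractions == (0.8, 0.2)
        # 80/20 of 80 per class -> 64 train, 16 test per class; verified via
        # the deviance paths being computed on 128/32 rows is internal, so we
        # check the public invariant instead: AUCs exist and are in range
        assert 0.0 <= report.auc_test <= 1.0

    def test_depth_two_trees_have_two_splits(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 3))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(float)  # needs interaction
        table = make_table(X, y)
        model, _ = pr.fit_brt(
            table, tree_complexity=2, bag_fraction=1.0, max_trees=5, seed=0
        )
        n_internal = sum(1 for nd in model.trees[0].walk() if not nd.is_leaf)
        assert n_internal == 2


class TestPredictSuitability:
    def test_intercept_only_uniform_map(self, small_world):
        _, present, _ = small_world
        model = pr.BoostedModel(
            intercept=0.0, trees=[], variables=["bio01"], learning_rate=0.1,
            tree_complexity=1, bag_fraction=0.5, seed=0, n_trees_used=0,
        )
        suit = pr.predict_suitability(model, present)
        np.testing.assert_allclose(suit, 0.5)

    def test_projection_equals_rowwise_prediction(self, small_world, cold_species_setup):
        _, present, _ = small_world
        *_, table = cold_species_setup
        model, _ = pr.fit_brt(table, max_trees=20, seed=0)
        suit = pr.predict_suitability(model, present)
        rows = np.array([present.grid.cell_of(x, y) for x, y in zip(table.x, table.y)])
        grid_vals = suit[rows[:, 0], rows[:, 1]]
        direct = model.predict_proba(model.matrix_from_table(table))
        np.testing.assert_allclose(grid_vals, direct)

    def test_missing_variable_named_in_error(self, small_world):
        _, present, _ = small_world
        model = pr.BoostedModel(
            intercept=0.0, trees=[], variables=["bio99"], learning_rate=0.1,
            tree_complexity=1, bag_fraction=0.5, seed=0,
        )
        with pytest.raises(ValueError, match="bio99"):
            pr.predict_suitability(model, present)

    def test_monotone_stump_shifts_with_warming(self, small_world):
        _, present, _ = small_world
        # one stump: suitability higher below 10 degrees (a cold-adapted form)
        stump = TreeNode(variable=0, split=10.0, left=TreeNode(value=2.0),
                         right=TreeNode(value=-2.0))
        model = pr.BoostedModel(
            intercept=0.0, trees=[stump], variables=["bio01"], learning_rate=1.0,
            tree_complexity=1, bag_fraction=1.0, seed=0, n_trees_used=1,
        )
        warmer = pr.ClimateStack(
            grid=present.grid, variables=present.variables,
            values={k: v + 5.0 for k, v in present.values.items()},
            nodata_mask=present.nodata_mask.copy(), scenario_id="warm",
        )
        s_now = pr.predict_suitability(model, present)
        s_warm = pr.predict_suitability(model, warmer)
        assert (s_warm <= s_now + 1e-12).all()
        assert s_warm.sum() < s_now.sum()


class TestAuc:
    def test_worked_examples(self):
        assert pr.auc([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.2]) == pytest.approx(0.75)
        assert pr.auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert pr.auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pr.auc([1, 1], [0.2, 0.3])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        scores=st.lists(st.floats(0, 1, allow_nan=False), min_size=4, max_size=30),
        labels=st.data(),
    )
    def test_matches_pair_counting_oracle(self, scores, labels):
        y = [labels.draw(st.integers(0, 1)) for _ in scores]
        if len(set(y)) < 2:
            y[0], y[1] = 0, 1
        y, s = np.array(y, float), np.array(scores)
        # brute-force enumeration of all (positive, negative) pairs
        pos, neg = s[y == 1], s[y == 0]
        conc = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
        assert pr.auc(y, s) == pytest.approx(conc / (len(pos) * len(neg)))

    def test_agrees_with_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        s = rng.random(200)
        assert pr.auc(y, s) == pytest.approx(sklearn_metrics.roc_auc_score(y, s))


class TestVariableImportance:
    def test_single_variable_gets_all_importance(self):
        x = np.linspace(-1, 1, 40)
        X = np.column_stack([x, np.zeros(40)])  # second variable constant
        y = (x > 0).astype(float)
        model, _ = pr.fit_brt(
            make_table(X, y), bag_fraction=1.0, max_trees=10, seed=0
        )
        imp = pr.variable_importance(model)
        assert imp["v0"] == pytest.approx(100.0)
        assert imp["v1"] == 0.0

    def test_importances_sum_to_100(self, cold_species_setup):
        *_, table = cold_species_setup
        model, _ = pr.fit_brt(table, max_trees=30, seed=2)
        imp = pr.variable_importance(model)
        assert sum(imp.values()) == pytest.approx(100.0, abs=1e-9)
        assert all(v >= 0 for v in imp.values())

    def test_intercept_only_warns_all_zero(self):
        model = pr.BoostedModel(
            intercept=0.3, trees=[], variables=["a", "b"], learning_rate=0.1,
            tree_complexity=1, bag_fraction=0.5, seed=0, n_trees_used=0,
        )
        with pytest.warns(UserWarning, match="no splits"):
            imp = pr.variable_importance(model)
        assert imp == {"a": 0.0, "b": 0.0}


class TestPartialDependence:
    def test_intercept_only_flat_at_prevalence(self):
        X = np.random.default_rng(0).random((20, 2))
        model = pr.BoostedModel(
            intercept=np.log(0.25 / 0.75), trees=[], variables=["a", "b"],
            learning_rate=0.1, tree_complexity=1, bag_fraction=0.5, seed=0,
            n_trees_used=0, calibration_rows=X,
        )
        _, resp = partial_dependence(model, "a", 10)
        np.testing.assert_allclose(resp, 0.25)

    def test_single_stump_two_level_step(self):
        X = np.linspace(0, 1, 21)[:, None]
        stump = TreeNode(variable=0, split=0.5, left=TreeNode(value=-1.0),
                         right=TreeNode(value=1.0))
        model = pr.BoostedModel(
            intercept=0.0, trees=[stump], variables=["a"], learning_rate=1.0,
            tree_complexity=1, bag_fraction=1.0, seed=0, n_trees_used=1,
            calibration_rows=X,
        )
        probes, resp = partial_dependence(model, "a", 40)
        assert set(np.round(resp, 6)) <= {
            round(1 / (1 + np.exp(1)), 6), round(1 / (1 + np.exp(-1)), 6)
        }
        assert resp[probes < 0.5].max() < resp[probes > 0.5].min()

    def test_unknown_variable_rejected(self):
        model = pr.BoostedModel(
            intercept=0.0, trees=[], variables=["a"], learning_rate=0.1,
            tree_complexity=1, bag_fraction=0.5, seed=0,
        )
        with pytest.raises(ValueError, match="zzz"):
            partial_dependence(model, "zzz")

    def test_unimodal_recovery_of_synthetic_optimum(self, small_world, cold_species_setup):
        truth, _, _, table = cold_species_setup
        model, _ = pr.fit_brt(table, max_trees=200, seed=0)
        est = pd_optimum(model, "bio01")
        assert abs(est - truth.optimum[0]) <= truth.breadth[0]


class TestSerialization:
    def test_round_trip_bit_exact(self, cold_species_setup, tmp_path):
        *_, table = cold_species_setup
        model, _ = pr.fit_brt(table, max_trees=25, seed=4)
        save_model(tmp_path / "m.json", model)
        loaded = load_model(tmp_path / "m.json")
        assert loaded.intercept == model.intercept
        assert loaded.n_trees_used == model.n_trees_used
        X = model.calibration_rows
        np.testing.assert_array_equal(
            loaded.decision_function(X), model.decision_function(X)
        )

    def test_leaf_values_bounded(self, cold_species_setup):
        *_, table = cold_species_setup
        model, _ = pr.fit_brt(table, max_trees=50, seed=5)
        for tree in model.trees:
            for node in tree.walk():
                if node.is_leaf:
                    assert abs(node.value) <= LEAF_CLIP
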