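"""The cost-sensitive categorical tree learner."""

import math

import numpy as np
import pytest

from spiketree import c5tree as ct
from conftest import make_interval_table, random_interval_table


class TestConfigTypes:
    def test_validation(self):
        with pytest.raises(ValueError):
            ct.CostMatrix(fn_cost=-1)
        with pytest.raises(ValueError):
            ct.FitConfig(trials=0)
        with pytest.raises(ValueError):
            ct.FitConfig(prune_confidence=1.5)

    def test_minimum_expected_cost_leaf_class(self):
        costs = ct.CostMatrix()  # fn=3.5, fp=1
        # 5 negatives, 2 positives: predicting 0 costs 2*3.5=7 > predicting 1 costs 5
        assert costs.leaf_class(w0=5, w1=2) == 1
        assert costs.leaf_class(w0=8, w1=2) == 0
        assert ct.CostMatrix(1, 1).leaf_class(w0=3, w1=3) == 0  # tie -> class 0


class TestFitAndPredict:
    def test_perfect_predictor_yields_one_split_tree(self):
        tab = make_interval_table(["A", "0", "A", "0", "A", "0"], [1, 0, 1, 0, 1, 0])
        model = ct.fit_tree(tab)
        np.testing.assert_array_equal(ct.predict(model, tab), tab.y)
        assert ct.variable_importance(model) == {"U1": 100.0}
        assert ct.primary_group(model) == {"U1"}
        assert model.trees[0][0].n_leaves() == 2

    def test_four_row_table_has_zero_training_error(self):
        tab = make_interval_table(["A", "0", "A", "0"], [1, 0, 1, 0])
        model = ct.fit_tree(tab)
        assert int(np.sum(ct.predict(model, tab) != tab.y)) == 0

    def test_single_class_input_degenerates_with_warning(self):
        tab = make_interval_table(["A", "B", "0", "A"], [1, 1, 1, 1])
        with pytest.warns(UserWarning, match="single-class"):
            model = ct.fit_tree(tab)
        assert model.is_stump
        assert np.all(ct.predict(model, tab) == 1)

    def test_uninformative_attributes_yield_stump(self):
        tab = make_interval_table(["A", "A", "A", "A"], [1, 0, 1, 0])
        model = ct.fit_tree(tab)
        assert model.is_stump
        assert ct.primary_group(model) == set()

    def test_single_leaf_class0_predicts_all_zero(self):
        tab = make_interval_table(["A", "A", "A", "A", "A"], [0, 0, 0, 0, 1])
        model = ct.fit_tree(tab)
        assert model.is_stump          # one category -> nothing to split on
        assert np.all(ct.predict(model, tab) == 0)  # 1*3.5 < 4*1 -> class 0

    def test_unseen_category_routes_to_fallback(self):
        tab = make_interval_table(["A", "A", "0", "0", "0"], [1, 1, 0, 0, 0])
        model = ct.fit_tree(tab)
        frame = tab.data.copy()
        frame.loc[0, "U1"] = "ZZZ"  # never seen in training
        pred = ct.predict(model, frame)
        assert set(np.unique(pred)) <= {0, 1}
        # fallback branch is "0" (3 cases > 2 cases) -> unseen predicts 0
        assert pred[0] == 0

    def test_missing_attribute_column_is_named(self):
        tab = make_interval_table(["A", "0"], [1, 0])
        model = ct.fit_tree(tab)
        with pytest.raises(KeyError, match="U1"):
            ct.predict(model, tab.data.drop(columns=["U1"]))

    def test_determinism(self):
        rng = np.random.default_rng(5)
        tab = random_interval_table(rng, n_rows=200, n_units=4, informative=2)
        a = ct.fit_tree(tab).to_dict()
        b = ct.fit_tree(tab).to_dict()
        assert a == b


def entropy(counts):
    n = sum(counts)
    return -sum(c / n * math.log2(c / n) for c in counts if c > 0)


def oracle_root_choice(codes, y, min_cases=2):
    """Exhaustive gain-ratio root selection (independent re-implementation)."""
    n, k = codes.shape
    parent = entropy(np.bincount(y, minlength=2))
    usable, gains, ratios = [], {}, {}
    for a in range(k):
        cats, counts = np.unique(codes[:, a], return_counts=True)
        if len(cats) < 2 or np.sum(counts >= min_cases) < 2:
            continue
        cond = split_info = 0.0
        for c, nc in zip(cats, counts):
            frac = nc / n
            cond += frac * entropy(np.bincount(y[codes[:, a] == c], minlength=2))
            split_info -= frac * math.log2(frac)
        gain = parent - cond
        if gain <= 1e-12 or split_info <= 1e-12:
            continue
        usable.append(a)
        gains[a], ratios[a] = gain, gain / split_info
    if not usable:
        return None
    avg = sum(gains[a] for a in usable) / len(usable)
    best = None
    for a in usable:
        if gains[a] >= avg - 1e-12 and (best is None or ratios[a] > ratios[best] + 1e-12):
            best = a
    return best


class TestGainRatioOracle:
    def test_root_attribute_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(12)
        checked = 0
        for _ in range(300):
            n_rows = int(rng.integers(8, 16))
            codes = rng.choice(np.array(["0", "A", "B"], dtype=object), size=(n_rows, 2))
            y = rng.integers(0, 2, n_rows)
            if y.min() == y.max():
                continue
            tab = make_interval_table(codes, y)
            model = ct.fit_tree(tab, cfg=ct.FitConfig(prune_confidence=0.25))
            root = model.trees[0][0]
            expect = oracle_root_choice(codes, y)
            if expect is None:
                assert root.is_leaf
            elif not root.is_leaf:  # pruning may legitimately collapse the tree
                assert root.attr == expect
                checked += 1
        assert checked >= 50  # the oracle actually exercised non-trivial trees


class TestImportance:
    def test_second_level_split_scores_its_case_share(self):
        # U1 splits 80 cases into X (30, pure 1), X2 (30, pure 0) and Y (20,
        # mixed, resolved by U2) -> importance(U2) = 20/80 = 25%
        codes, y = [], []
        for i in range(30):
            codes.append(["X", "0"])
            y.append(1)
        for i in range(30):
            codes.append(["X2", "0"])
            y.append(0)
        for i in range(20):
            codes.append(["Y", "A" if i % 2 else "0"])
            y.append(1 if i % 2 else 0)
        tab = make_interval_table(np.array(codes, dtype=object), y)
        model = ct.fit_tree(tab, costs=ct.CostMatrix(1, 1))
        imp = ct.variable_importance(model)
        assert imp["U1"] == 100.0
        assert imp["U2"] == pytest.approx(25.0)  # 20 of 80 cases reach the U2 split
        assert ct.primary_group(model) == {"U1", "U2"}

    def test_unused_attribute_scores_zero(self):
        tab = make_interval_table(
            [["A", "0"], ["0", "0"], ["A", "0"], ["0", "0"]], [1, 0, 1, 0]
        )
        imp = ct.variable_importance(ct.fit_tree(tab))
        assert imp["U2"] == 0.0


class TestPruning:
    def test_pruned_tree_is_never_larger(self, monkeypatch):
        rng = np.random.default_rng(9)
        for _ in range(20):
            tab = random_interval_table(rng, n_rows=120, n_units=3, informative=0)
            # flip some labels to create noise worth pruning
            noisy = tab.data["R"].to_numpy().copy()
            flip = rng.random(len(noisy)) < 0.15
            noisy[flip] = 1 - noisy[flip]
            tab.data["R"] = noisy
            pruned = ct.fit_tree(tab)
            with monkeypatch.context() as m:
                m.setattr(ct, "_prune", lambda node, costs, cf: (node, 0.0))
                unpruned = ct.fit_tree(tab)
            assert pruned.trees[0][0].n_leaves() <= unpruned.trees[0][0].n_leaves()


class TestCosts:
    def test_raising_fn_cost_weakly_increases_recall(self):
        rng = np.random.default_rng(21)
        codes = rng.choice(np.array(["0", "A", "B", "C"], dtype=object), size=(300, 2))
        base = (codes[:, 0] != "0").astype(int)
        flip = rng.random(300) < 0.25
        y = np.where(flip, 1 - base, base)
        tab = make_interval_table(codes, y)
        recalls = []
        for fn in (0.5, 1.0, 2.0, 3.5, 8.0):
            model = ct.fit_tree(tab, costs=ct.CostMatrix(fn_cost=fn))
            pred = ct.predict(model, tab)
            tp = np.sum((pred == 1) & (y == 1))
            recalls.append(tp / max(1, np.sum(y == 1)))
        assert all(b >= a - 1e-12 for a, b in zip(recalls, recalls[1:]))


class TestRules:
    def test_rules_reproduce_predictions_on_random_rows(self):
        rng = np.random.default_rng(33)
        tab = random_interval_table(rng, n_rows=300, n_units=3, informative=1)
        model = ct.fit_tree(tab)
        rules = ct.extract_rules(model)
        cats = np.array(["0", "A", "B", "AB", "C", "ZZ"], dtype=object)  # ZZ unseen
        frame = tab.data.sample(n=1000, replace=True, random_state=0).reset_index(drop=True)
        frame["U2"] = rng.choice(cats, size=1000)
        np.testing.assert_array_equal(
            ct.apply_rules(rules, frame), ct.predict(model, frame)
        )

    def test_rule_count_and_unconditional_rule(self):
        tab = make_interval_table(["A", "0", "A", "0"], [1, 0, 1, 0])
        rules = ct.extract_rules(ct.fit_tree(tab))
        assert len(rules) == 2
        stump = ct.fit_tree(make_interval_table(["A", "A", "A", "A"], [1, 0, 1, 0]))
        (rule,) = ct.extract_rules(stump)
        assert rule.tests == ()
        assert "TRUE" in rule.describe()

    def test_boosted_committee_refuses_rule_extraction(self):
        rng = np.random.default_rng(4)
        tab = random_interval_table(rng, n_rows=100, n_units=2, informative=0)
        noisy = tab.data["R"].to_numpy().copy()
        noisy[rng.random(100) < 0.2] ^= 1
        tab.data["R"] = noisy
        model = ct.fit_tree(tab, cfg=ct.FitConfig(trials=5))
        if len(model.trees) > 1:
            with pytest.raises(ValueError, match="trials=1"):
                ct.extract_rules(model)


class TestBoosting:
    def test_committee_predictions_stay_binary_and_deterministic(self):
        rng = np.random.default_rng(8)
        tab = random_interval_table(rng, n_rows=200, n_units=3, informative=0)
        noisy = tab.data["R"].to_numpy().copy()
        noisy[rng.random(200) < 0.2] ^= 1
        tab.data["R"] = noisy
        m1 = ct.fit_tree(tab, cfg=ct.FitConfig(trials=5))
        m2 = ct.fit_tree(tab, cfg=ct.FitConfig(trials=5))
        pred = ct.predict(m1, tab)
        assert set(np.unique(pred)) <= {0, 1}
        np.testing.assert_array_equal(pred, ct.predict(m2, tab))

    def test_trials_one_committee_equals_its_tree(self):
        rng = np.random.default_rng(2)
        tab = random_interval_table(rng, n_rows=150, n_units=2, informative=0)
        model = ct.fit_tree(tab, cfg=ct.FitConfig(trials=1))
        assert len(model.trees) == 1
        tree_pred = ct._route_predict(
            model.trees[0][0],
            ct._encode_frame(tab.data, model.attributes, model.categories),
            np.arange(tab.n_rows),
        )
        np.testing.assert_array_equal(ct.predict(model, tab), tree_pred)


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(6)
        tab = random_interval_table(rng, n_rows=150, n_units=3, informative=2)
        model = ct.fit_tree(tab)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ct.TreeModel.from_json(path)
        np.testing.assert_array_equal(ct.predict(back, tab), ct.predict(model, tab))
        assert back.importance == model.importance
        with pytest.raises(ValueError, match="format"):
            ct.TreeModel.from_dict({"format_version": 99})
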