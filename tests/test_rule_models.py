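"""CDI induction: Gini machinery, CART tree/rule list, ensemble, reference rule."""
import json
import warnings

import numpy as np
import pandas as pd
import pytest

import cdivet.rule_models as rm
import cdivet.synth_cohort as sc
from cdivet.preprocess import preprocess_cohort

from conftest import random_binary_cohort


# ---------------------------------------------------------------------------
# Independent exhaustive-enumeration oracle (loops and explicit arithmetic;
# no shared code with the implementation)
# ---------------------------------------------------------------------------


def oracle_gini(pos, neg, w):
    wp, wn = w * pos, neg
    p = wp / (wp + wn)
    return 1 - p * p - (1 - p) * (1 - p)


def oracle_candidates(table):
    out = []
    for col in table.columns:
        vals = sorted(set(table[col]))
        if set(vals) <= {0.0, 1.0}:
            out.append((col, "==", 1.0))
        else:
            for lo, hi in zip(vals, vals[1:]):
                out.append((col, "<", (lo + hi) / 2))
    return out


def oracle_fires(table, cond):
    col, op, thr = cond
    values = list(table[col])
    if op == "==":
        return [v == thr for v in values]
    return [v < thr for v in values]


def oracle_best_split(table, y, w=1.0, min_leaf=1):
    y = list(y)
    if len(y) < 2 or len(set(y)) < 2:
        return None
    pos = sum(y)
    neg = len(y) - pos
    parent = oracle_gini(pos, neg, w)
    W = w * pos + neg
    best = None
    for cond in oracle_candidates(table):
        fires = oracle_fires(table, cond)
        n1 = sum(fires)
        n0 = len(y) - n1
        if n1 < min_leaf or n0 < min_leaf or n1 == 0 or n0 == 0:
            continue
        p1 = sum(yy for yy, f in zip(y, fires) if f)
        p0 = pos - p1
        w1 = w * p1 + (n1 - p1)
        w0 = w * p0 + (n0 - p0)
        child = (w1 * oracle_gini(p1, n1 - p1, w) + w0 * oracle_gini(p0, n0 - p0, w)) / W
        dec = parent - child
        if best is None or dec > best[1]:
            best = (cond, dec)
    return best


def oracle_tree(table, y, w, max_depth, min_leaf, depth=0):
    y = list(y)
    pos = sum(y)
    risk = w * pos / (w * pos + (len(y) - pos))
    if depth >= max_depth:
        return {"risk": risk}
    found = oracle_best_split(table, y, w, min_leaf)
    if found is None or found[1] <= 0:
        return {"risk": risk}
    cond, _ = found
    fires = np.array(oracle_fires(table, cond))
    return {
        "cond": cond,
        "yes": oracle_tree(table[fires], np.array(y)[fires], w, max_depth, min_leaf, depth + 1),
        "no": oracle_tree(table[~fires], np.array(y)[~fires], w, max_depth, min_leaf, depth + 1),
    }


def tree_to_oracle_shape(node: rm.TreeNode):
    if node.is_leaf:
        return {"risk": node.risk}
    c = node.condition
    return {
        "cond": (c.predictor, c.op, float(c.threshold)),
        "yes": tree_to_oracle_shape(node.yes),
        "no": tree_to_oracle_shape(node.no),
    }


def trees_equal(a, b, tol=1e-12):
    if ("risk" in a) != ("risk" in b):
        return False
    if "risk" in a:
        return abs(a["risk"] - b["risk"]) < tol
    return (
        a["cond"] == b["cond"]
        and trees_equal(a["yes"], b["yes"], tol)
        and trees_equal(a["no"], b["no"], tol)
    )


# ---------------------------------------------------------------------------
# Gini and best_split
# ---------------------------------------------------------------------------


class TestGini:
    @pytest.mark.parametrize(
        "pos,neg,expected",
        [(5, 5, 0.5), (10, 0, 0.0), (3, 1, 0.375)],
    )
    def test_values(self, pos, neg, expected):
        assert rm.gini_impurity(pos, neg) == pytest.approx(expected)

    def test_empty_node_undefined(self):
        with pytest.raises(ValueError):
            rm.gini_impurity(0, 0)


class TestBestSplit:
    def test_perfect_separator_selected_with_parent_impurity_decrease(self, rng):
        table = pd.DataFrame(
            {
                "noise": rng.integers(0, 2, 20).astype(float),
                "signal": np.array([1.0] * 10 + [0.0] * 10),
            }
        )
        y = np.array([1] * 10 + [0] * 10)
        cond, dec = rm.best_split(table, y)
        assert cond == rm.RuleCondition("signal", "==", 1)
        assert dec == pytest.approx(rm.gini_impurity(10, 10))

    def test_tie_broken_by_column_order(self):
        table = pd.DataFrame({"b": [1.0, 1.0, 0.0, 0.0], "a": [1.0, 1.0, 0.0, 0.0]})
        cond, _ = rm.best_split(table, np.array([1, 1, 0, 0]))
        assert cond.predictor == "b"  # first column wins, not alphabetical

    def test_matches_oracle_on_random_tables(self, rng):
        for _ in range(30):
            cohort = random_binary_cohort(rng, n=30, p=6)
            got = rm.best_split(cohort.predictors, cohort.outcome.to_numpy())
            want = oracle_best_split(cohort.predictors, cohort.outcome.to_numpy())
            if want is None:
                assert got is None
                continue
            assert (got[0].predictor, got[0].op, float(got[0].threshold)) == want[0]
            assert got[1] == pytest.approx(want[1])

    def test_ordinal_midpoints(self):
        table = pd.DataFrame({"gcs": [3.0, 13.0, 14.0, 15.0, 15.0]})
        y = np.array([1, 1, 0, 0, 0])
        cond, _ = rm.best_split(table, y)
        assert cond == rm.RuleCondition("gcs", "<", 13.5)

    def test_no_admissible_split_signal(self):
        table = pd.DataFrame({"x": [1.0, 1.0, 1.0]})
        assert rm.best_split(table, np.array([1, 0, 1])) is None


# ---------------------------------------------------------------------------
# CART tree
# ---------------------------------------------------------------------------


class TestCartTree:
    def test_outcome_equals_predictor_gives_depth_one(self, tiny_cohort):
        tree = rm.fit_cart_tree(tiny_cohort, class_weight=1.0, min_leaf=1)
        assert tree.depth == 1
        assert tree.root.condition.predictor == "a"
        risks = rm.predict_risk(tree, tiny_cohort)
        np.testing.assert_array_equal(risks, tiny_cohort.outcome.to_numpy())

    def test_refit_identical(self, rng):
        cohort = random_binary_cohort(rng, n=80, p=5, signal={"x0": 2.0})
        t1 = rm.fit_cart_tree(cohort)
        t2 = rm.fit_cart_tree(cohort)
        assert rm.model_to_json(t1) == rm.model_to_json(t2)

    @pytest.mark.parametrize("class_weight", [1.0, 5.0])
    def test_matches_exhaustive_oracle(self, rng, class_weight):
        for _ in range(25):
            cohort = random_binary_cohort(rng, n=50, p=5, signal={"x0": 1.5, "x1": -1.0})
            got = rm.fit_cart_tree(
                cohort, max_depth=2, min_leaf=1, class_weight=class_weight
            )
            want = oracle_tree(
                cohort.predictors,
                cohort.outcome.to_numpy(),
                class_weight,
                max_depth=2,
                min_leaf=1,
            )
            assert trees_equal(tree_to_oracle_shape(got.root), want)

    def test_single_class_degenerates_with_warning(self):
        cohort = sc.Cohort(pd.DataFrame({"x": [0.0, 1.0]}), pd.Series([0, 0]))
        with pytest.warns(UserWarning, match="single-class"):
            tree = rm.fit_cart_tree(cohort)
        assert tree.root.is_leaf

    def test_agrees_with_recursive_partitioning_reference(self, rng):
        """Root-split optimality cross-checked against scikit-learn CART."""
        sklearn = pytest.importorskip("sklearn.tree")
        for _ in range(10):
            cohort = random_binary_cohort(rng, n=60, p=6, signal={"x2": 2.0})
            found = rm.best_split(cohort.predictors, cohort.outcome.to_numpy())
            if found is None:
                continue
            ref = sklearn.DecisionTreeClassifier(
                criterion="gini", max_depth=1, random_state=0
            ).fit(cohort.predictors, cohort.outcome)
            if ref.tree_.node_count == 1:
                continue
            n = cohort.n
            w_n = ref.tree_.weighted_n_node_samples
            ref_decrease = ref.tree_.impurity[0] - (
                w_n[1] * ref.tree_.impurity[1] + w_n[2] * ref.tree_.impurity[2]
            ) / n
            assert found[1] == pytest.approx(ref_decrease, abs=1e-12)


# ---------------------------------------------------------------------------
# CART rule list
# ---------------------------------------------------------------------------


class TestCartRuleList:
    def test_disjoint_or_structure(self):
        table = pd.DataFrame(
            {
                "a": [1, 1, 0, 0, 0, 0, 0, 0],
                "b": [0, 0, 1, 1, 0, 0, 0, 0],
            },
            dtype=float,
        )
        cohort = sc.Cohort(table, pd.Series([1, 1, 1, 1, 0, 0, 0, 0]))
        rl = rm.fit_cart_rule_list(cohort, class_weight=1.0, min_leaf=1)
        assert [c.predictor for c in rl.conditions[:2]] == ["a", "b"]
        assert rl.leaf_risks[:2] == [1.0, 1.0]
        assert rl.default_risk == 0.0

    def test_strong_predictors_recovered_in_risk_order(self):
        cfg = sc.pecarn_like_config(n=8000, seed=0)
        clean, _ = preprocess_cohort(sc.generate_cohort(cfg))
        rl = rm.fit_cart_rule_list(clean, max_rules=7, min_leaf=20)
        assert [c.predictor for c in rl.conditions[:3]] == [
            "abd_trauma_or_seatbelt_sign",
            "gcs",
            "abd_tenderness",
        ]
        assert rl.leaf_risks[0] > rl.leaf_risks[1] > rl.leaf_risks[2]

    def test_stops_when_no_admissible_split(self):
        table = pd.DataFrame({"a": [1.0, 1.0, 0.0, 0.0]})
        cohort = sc.Cohort(table, pd.Series([1, 0, 1, 0]))
        rl = rm.fit_cart_rule_list(cohort, class_weight=1.0, min_leaf=1)
        assert len(rl.conditions) == 0  # no split improves Gini

    def test_step_cap_enforced(self):
        with pytest.raises(ValueError, match="cap"):
            rm.fit_cart_rule_list(
                sc.Cohort(pd.DataFrame({"a": [0.0, 1.0]}), pd.Series([0, 1])),
                max_rules=11,
            )


# ---------------------------------------------------------------------------
# Rule ensemble
# ---------------------------------------------------------------------------


class TestRuleEnsemble:
    def test_single_informative_predictor(self, rng):
        cohort = random_binary_cohort(rng, n=200, p=4, signal={"x1": 4.0})
        ens = rm.fit_rule_ensemble(cohort, n_trees=5, tree_depth=1, seed=0)
        assert "x1" in ens.variables

    def test_deterministic_under_seed(self, rng):
        cohort = random_binary_cohort(rng, n=150, p=4, signal={"x0": 3.0})
        e1 = rm.fit_rule_ensemble(cohort, seed=11)
        e2 = rm.fit_rule_ensemble(cohort, seed=11)
        assert rm.model_to_json(e1) == rm.model_to_json(e2)

    def test_selected_set_beats_every_single_rule(self, rng):
        cohort = random_binary_cohort(rng, n=100, p=5, signal={"x0": 2.0, "x3": 1.0})
        y = cohort.outcome.to_numpy()
        ens = rm.fit_rule_ensemble(cohort, n_trees=10, tree_depth=2, seed=1)

        def wscore(mask):
            sens = (mask & (y == 1)).sum() / max((y == 1).sum(), 1)
            spec = (~mask & (y == 0)).sum() / max((y == 0).sum(), 1)
            return (5 * sens + spec) / 6

        selected = np.zeros(cohort.n, dtype=bool)
        act = ens.activations(cohort)
        for j in range(act.shape[1]):
            selected |= act[:, j].astype(bool)
        best_single = wscore(selected)
        # brute force every candidate single rule minable at this depth
        tree = rm.fit_cart_tree(cohort, max_depth=2, min_leaf=10)
        # any single rule is a root-to-node path; compare against each predictor alone
        for col in cohort.predictors.columns:
            for val in (0, 1):
                mask = cohort.predictors[col].to_numpy() == val
                assert best_single >= wscore(mask) - 1e-9


# ---------------------------------------------------------------------------
# Reference CDI and prediction contract
# ---------------------------------------------------------------------------


def reference_schema_frame(n=1):
    cols = {name: np.zeros(n) for name, _, _ in rm.DEFAULT_REFERENCE_CONDITIONS}
    frame = pd.DataFrame(cols)
    frame["gcs"] = 15.0
    return frame


class TestReferenceCdi:
    def test_all_negative_patient_is_very_low_risk(self):
        cdi = rm.pecarn_reference_cdi()
        frame = reference_schema_frame()
        assert not cdi.fires_any(frame)[0]
        assert rm.predict_risk(cdi, frame)[0] == cdi.default_risk

    def test_gcs_13_fires_second_condition(self):
        cdi = rm.pecarn_reference_cdi()
        frame = reference_schema_frame()
        frame.loc[0, "gcs"] = 13.0
        assert cdi.first_match(frame)[0] == 1
        assert rm.predict_risk(cdi, frame)[0] == cdi.leaf_risks[1]

    def test_truncation_equivalent_when_weak_predictors_silent(self):
        # external cohort where the four weak findings never occur
        cfg = sc.pedsrc_like_config(n=1500)
        cfg = sc.shift_site(
            cfg,
            prevalence={name: 0.0 for name in sc.weak_predictors()},
        )
        cohort = sc.generate_cohort(cfg)
        table = cohort.predictors.fillna(0.0)
        cdi7 = rm.pecarn_reference_cdi()
        cdi3 = rm.truncate_rule_list(cdi7, 3)
        np.testing.assert_array_equal(cdi7.fires_any(table), cdi3.fires_any(table))

    def test_missing_column_is_schema_error(self):
        cdi = rm.pecarn_reference_cdi()
        with pytest.raises(rm.SchemaError):
            rm.predict_risk(cdi, pd.DataFrame({"gcs": [15.0]}))

    def test_missing_values_rejected(self):
        cdi = rm.pecarn_reference_cdi()
        frame = reference_schema_frame(2)
        frame.loc[0, "abd_tenderness"] = np.nan
        with pytest.raises(ValueError, match="impute"):
            rm.predict_risk(cdi, frame)


class TestPredictRisk:
    def test_rule_list_matches_hand_trace(self, rng):
        rl = rm.RuleList(
            [
                rm.RuleCondition("a", "==", 1),
                rm.RuleCondition("g", "<", 14),
                rm.RuleCondition("b", "==", 1),
            ],
            [0.5, 0.3, 0.1],
            0.01,
        )
        table = pd.DataFrame(
            {
                "a": rng.integers(0, 2, 20).astype(float),
                "b": rng.integers(0, 2, 20).astype(float),
                "g": rng.integers(3, 16, 20).astype(float),
            }
        )
        expected = []
        for _, row in table.iterrows():
            if row["a"] == 1:
                expected.append(0.5)
            elif row["g"] < 14:
                expected.append(0.3)
            elif row["b"] == 1:
                expected.append(0.1)
            else:
                expected.append(0.01)
        np.testing.assert_allclose(rm.predict_risk(rl, table), expected)

    def test_pure_tree_risks_are_zero_one(self, tiny_cohort):
        tree = rm.fit_cart_tree(tiny_cohort, class_weight=1.0, min_leaf=1)
        assert set(rm.predict_risk(tree, tiny_cohort)) <= {0.0, 1.0}


class TestRefitRandomness:
    def test_deterministic_fitters_have_zero_spread(self, rng):
        cohort = random_binary_cohort(rng, n=120, p=4, signal={"x0": 2.0})
        for fitter in (
            lambda seed: rm.fit_cart_tree(cohort),
            lambda seed: rm.fit_cart_rule_list(cohort),
        ):
            spread = rm.refit_randomness(fitter, cohort, n_seeds=3)
            assert spread.score_spread == 0.0
            assert spread.risk_spread == 0.0

    def test_seeded_ensemble_small_spread_with_strong_signal(self, rng):
        cohort = random_binary_cohort(rng, n=300, p=3, signal={"x0": 5.0})
        spread = rm.refit_randomness(
            lambda seed: rm.fit_rule_ensemble(cohort, n_trees=1, tree_depth=1, seed=seed),
            cohort,
            n_seeds=10,
        )
        assert spread.score_spread < 0.05

    def test_single_seed_rejected(self, tiny_cohort):
        with pytest.raises(ValueError):
            rm.refit_randomness(lambda s: rm.fit_cart_tree(tiny_cohort), tiny_cohort, n_seeds=1)


class TestSerialization:
    def test_roundtrip_all_model_types(self, rng):
        cohort = random_binary_cohort(rng, n=100, p=4, signal={"x0": 2.0})
        reference = rm.pecarn_reference_cdi()
        ref_back = rm.model_from_json(rm.model_to_json(reference))
        frame = reference_schema_frame(3)
        np.testing.assert_allclose(
            rm.predict_risk(ref_back, frame), rm.predict_risk(reference, frame)
        )
        models = [
            rm.fit_cart_tree(cohort),
            rm.fit_cart_rule_list(cohort),
            rm.fit_rule_ensemble(cohort, n_trees=5, seed=0),
            rm.fit_logistic(cohort),
        ]
        for model in models:
            back = rm.model_from_json(rm.model_to_json(model))
            np.testing.assert_allclose(
                rm.predict_risk(back, cohort), rm.predict_risk(model, cohort)
            )
            assert rm.render_text(model)  # renders without error

    def test_interpretability_cap_on_all_fits(self, rng):
        cohort = random_binary_cohort(rng, n=200, p=8, signal={"x0": 1.0})
        rl = rm.fit_cart_rule_list(cohort, max_rules=10, min_leaf=1)
        assert len(rl.conditions) <= 10
        ens = rm.fit_rule_ensemble(cohort, n_trees=20, max_rules=8, seed=0)
        assert len(ens.rules) <= 10


class TestClassWeightMonotonicity:
    def test_sensitivity_non_decreasing_in_weight(self, rng):
        from cdivet.diagnostics import confusion

        cohort = random_binary_cohort(rng, n=400, p=5, signal={"x0": 1.5, "x1": 1.0})
        y = cohort.outcome.to_numpy()
        last_sens = -1.0
        for w in (1.0, 5.0, 25.0, 125.0):
            rl = rm.fit_cart_rule_list(cohort, class_weight=w, min_leaf=5)
            fired = rl.fires_any(cohort)
            counts = confusion(y, fired)
            sens = counts.tp / max(counts.tp + counts.fn, 1)
            assert sens >= last_sens - 1e-12
            last_sens = sens
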