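"""Interpretable rule-based clinical decision instruments (CDIs).

All CDIs here are explicit IF/THEN structures over named patient findings:

* :class:`RuleList` -- an ordered list of (condition, risk) pairs with a
  default leaf; a patient takes the risk of the first condition that fires.
  The frozen seven-variable PECARN-style reference rule is a ``RuleList``
  with ``provenance='reference'``.
* :class:`DecisionTreeModel` -- a CART tree grown by binary recursive
  partitioning with the Gini criterion.
* :class:`RuleEnsembleModel` -- a small set of conjunctive rules mined from
  bagged shallow trees and combined through a logistic link (a parsimonious
  RuleFit-style model).
* :class:`LogisticModel` -- a plain linear-score baseline under the same
  risk-prediction contract.

Class imbalance (the outcome is rare, ~1.7%) is handled by an outcome-class
weight applied inside the impurity computation and the leaf risks; the
default weight of 5 mirrors the 5:1 sensitivity-over-specificity preference
used to screen CDIs downstream.  Every fitter is deterministic given its
inputs (and seed, where one exists): ties are broken by column order, then
by ascending threshold.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

MAX_LOGICAL_STEPS = 10  # interpretability cap: fewer than 10 rules/leaves

__all__ = [
    "RuleCondition",
    "RuleList",
    "DecisionTreeModel",
    "TreeNode",
    "RuleEnsembleModel",
    "LogisticModel",
    "SchemaError",
    "gini_impurity",
    "best_split",
    "fit_cart_tree",
    "fit_cart_rule_list",
    "fit_rule_ensemble",
    "fit_logistic",
    "pecarn_reference_cdi",
    "predict_risk",
    "refit_randomness",
    "RefitSpread",
    "model_variables",
    "model_to_json",
    "model_from_json",
    "render_text",
    "truncate_rule_list",
    "DEFAULT_REFERENCE_CONDITIONS",
    "DEFAULT_REFERENCE_RISKS",
    "DEFAULT_REFERENCE_DEFAULT_RISK",
]


class SchemaError(KeyError):
    """A model references a predictor absent from the cohort schema."""


# ---------------------------------------------------------------------------
# Conditions
# ---------------------------------------------------------------------------

_OPS = ("==", "<", ">=")


@dataclass(frozen=True)
class RuleCondition:
    """A single atomic clinical finding test, e.g. ``gcs < 14``."""

    predictor: str
    op: str
    threshold: float

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"unsupported operator {self.op!r}")

    def evaluate(self, table: pd.DataFrame) -> np.ndarray:
        if self.predictor not in table.columns:
            raise SchemaError(self.predictor)
        col = table[self.predictor].to_numpy()
        if np.isnan(col.astype(float)).any():
            raise ValueError(
                f"column {self.predictor!r} contains missing values; impute first"
            )
        if self.op == "==":
            return col == self.threshold
        if self.op == "<":
            return col < self.threshold
        return col >= self.threshold

    def negate(self) -> "RuleCondition":
        if self.op == "==":
            # binary flags only: == 1 <-> == 0
            return RuleCondition(self.predictor, "==", 1 - self.threshold)
        if self.op == "<":
            return RuleCondition(self.predictor, ">=", self.threshold)
        return RuleCondition(self.predictor, "<", self.threshold)

    def __str__(self) -> str:
        thr = int(self.threshold) if float(self.threshold).is_integer() else self.threshold
        return f"{self.predictor} {self.op} {thr}"


def _as_table(cohort) -> pd.DataFrame:
    """Accept either a Cohort-like object or a bare predictor DataFrame."""
    return getattr(cohort, "predictors", cohort)


# ---------------------------------------------------------------------------
# Model classes
# ---------------------------------------------------------------------------


@dataclass
class RuleList:
    """Ordered (condition -> leaf risk) list with a default leaf.

    A patient is assigned the risk of the *first* condition that fires;
    patients matching no condition take ``default_risk``.  Under the
    screening contract a patient is "very low risk" iff no condition fires.
    """

    conditions: list[RuleCondition]
    leaf_risks: list[float]
    default_risk: float
    provenance: str = "fitted"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.conditions) != len(self.leaf_risks):
            raise ValueError("conditions and leaf_risks length mismatch")
        if len(self.conditions) > MAX_LOGICAL_STEPS:
            raise ValueError("rule list exceeds the interpretability cap")
        risks = list(self.leaf_risks) + [self.default_risk]
        if any(not (0.0 <= r <= 1.0) for r in risks):
            raise ValueError("risks must lie in [0, 1]")
        if self.provenance == "reference":
            if any(b >= a for a, b in zip(self.leaf_risks, self.leaf_risks[1:])):
                raise ValueError("reference leaf risks must strictly decrease")
            if self.conditions and self.default_risk >= self.leaf_risks[-1]:
                raise ValueError("reference default risk must be below the last leaf")

    # -- prediction ---------------------------------------------------------

    def first_match(self, cohort) -> np.ndarray:
        """Index of the first firing condition per row (len(conditions) = default)."""
        table = _as_table(cohort)
        n = len(table)
        out = np.full(n, len(self.conditions), dtype=int)
        unmatched = np.ones(n, dtype=bool)
        for i, cond in enumerate(self.conditions):
            fires = cond.evaluate(table) & unmatched
            out[fires] = i
            unmatched &= ~fires
        return out

    def predict(self, cohort) -> np.ndarray:
        risks = np.asarray(list(self.leaf_risks) + [self.default_risk])
        return risks[self.first_match(cohort)]

    def fires_any(self, cohort) -> np.ndarray:
        """Classification contract: positive (not very low risk) iff any condition fires."""
        return self.first_match(cohort) < len(self.conditions)

    @property
    def variables(self) -> list[str]:
        seen: list[str] = []
        for c in self.conditions:
            if c.predictor not in seen:
                seen.append(c.predictor)
        return seen


@dataclass
class TreeNode:
    """Internal node (condition, yes, no) or leaf (risk)."""

    condition: RuleCondition | None = None
    yes: "TreeNode | None" = None
    no: "TreeNode | None" = None
    risk: float | None = None
    n: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.condition is None


@dataclass
class DecisionTreeModel:
    root: TreeNode
    provenance: str = "fitted"
    params: dict = field(default_factory=dict)

    def predict(self, cohort) -> np.ndarray:
        table = _as_table(cohort)
        out = np.empty(len(table), dtype=float)

        def walk(node: TreeNode, idx: np.ndarray) -> None:
            if node.is_leaf:
                out[idx] = node.risk
                return
            fires = node.condition.evaluate(table.iloc[idx])
            walk(node.yes, idx[fires])
            walk(node.no, idx[~fires])

        walk(self.root, np.arange(len(table)))
        return out

    @property
    def depth(self) -> int:
        def d(node: TreeNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(d(node.yes), d(node.no))

        return d(self.root)

    @property
    def n_leaves(self) -> int:
        def c(node: TreeNode) -> int:
            return 1 if node.is_leaf else c(node.yes) + c(node.no)

        return c(self.root)

    @property
    def variables(self) -> list[str]:
        seen: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                return
            if node.condition.predictor not in seen:
                seen.append(node.condition.predictor)
            walk(node.yes)
            walk(node.no)

        walk(self.root)
        return seen


@dataclass
class RuleEnsembleModel:
    """Sparse set of conjunctive rules combined through a logistic link."""

    rules: list[list[RuleCondition]]
    weights: list[float]
    intercept: float
    provenance: str = "fitted"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.rules) > MAX_LOGICAL_STEPS:
            raise ValueError("rule ensemble exceeds the interpretability cap")

    def activations(self, cohort) -> np.ndarray:
        table = _as_table(cohort)
        if not self.rules:
            return np.zeros((len(table), 0))
        cols = []
        for rule in self.rules:
            fires = np.ones(len(table), dtype=bool)
            for cond in rule:
                fires &= cond.evaluate(table)
            cols.append(fires)
        return np.column_stack(cols).astype(float)

    def predict(self, cohort) -> np.ndarray:
        act = self.activations(cohort)
        return expit(self.intercept + act @ np.asarray(self.weights))

    @property
    def variables(self) -> list[str]:
        seen: list[str] = []
        for rule in self.rules:
            for c in rule:
                if c.predictor not in seen:
                    seen.append(c.predictor)
        return seen


@dataclass
class LogisticModel:
    """Threshold-on-linear-score baseline under the common risk contract."""

    predictors: list[str]
    coef: list[float]
    intercept: float
    provenance: str = "fitted"
    params: dict = field(default_factory=dict)

    def predict(self, cohort) -> np.ndarray:
        table = _as_table(cohort)
        missing = [p for p in self.predictors if p not in table.columns]
        if missing:
            raise SchemaError(missing[0])
        X = table[self.predictors].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError("missing values present; impute first")
        return expit(self.intercept + X @ np.asarray(self.coef))

    @property
    def variables(self) -> list[str]:
        return [p for p, c in zip(self.predictors, self.coef) if c != 0.0]


Model = RuleList | DecisionTreeModel | RuleEnsembleModel | LogisticModel


def predict_risk(model: Model, cohort) -> np.ndarray:
    """Common prediction contract: per-patient risk in [0, 1]."""
    risks = model.predict(cohort)
    if np.any((risks < 0) | (risks > 1)):
        raise ValueError("model produced risks outside [0, 1]")
    return np.asarray(risks, dtype=float)


def model_variables(model: Model) -> list[str]:
    return model.variables


# ---------------------------------------------------------------------------
# CART machinery
# ---------------------------------------------------------------------------


def gini_impurity(pos: float, neg: float) -> float:
    """Gini impurity 1 - p^2 - (1-p)^2 of a node with (weighted) class counts."""
    total = pos + neg
    if total <= 0:
        raise ValueError("gini impurity undefined for an empty node")
    p = pos / total
    return 1.0 - p * p - (1.0 - p) * (1.0 - p)


def _is_binary(col: np.ndarray) -> bool:
    vals = np.unique(col)
    return np.isin(vals, (0.0, 1.0)).all()


def candidate_conditions(table: pd.DataFrame) -> list[RuleCondition]:
    """All admissible split conditions, in tie-break order.

    Binary flags contribute ``== 1``; ordinal columns contribute ``< t`` at
    every mid-point between adjacent observed values, thresholds ascending.
    """
    cands: list[RuleCondition] = []
    for col in table.columns:
        vals = table[col].to_numpy(dtype=float)
        if _is_binary(vals):
            cands.append(RuleCondition(col, "==", 1))
        else:
            uniq = np.unique(vals)
            for lo, hi in zip(uniq, uniq[1:]):
                cands.append(RuleCondition(col, "<", (lo + hi) / 2.0))
    return cands


def _weighted_counts(y: np.ndarray, class_weight: float) -> tuple[float, float]:
    pos = float(y.sum()) * class_weight
    neg = float(len(y) - y.sum())
    return pos, neg


def best_split(
    table: pd.DataFrame,
    y: np.ndarray,
    *,
    class_weight: float = 1.0,
    min_leaf: int = 1,
    candidates: Sequence[RuleCondition] | None = None,
) -> tuple[RuleCondition, float] | None:
    """Condition maximizing the size-weighted Gini decrease, or None.

    Ties are broken by column order then ascending threshold (the candidate
    enumeration order); sides with fewer than ``min_leaf`` rows are
    inadmissible.
    """
    y = np.asarray(y)
    if len(y) < 2 or y.min() == y.max():
        return None
    if candidates is None:
        candidates = candidate_conditions(table)
    pos_p, neg_p = _weighted_counts(y, class_weight)
    parent = gini_impurity(pos_p, neg_p)
    w_parent = pos_p + neg_p
    best: tuple[RuleCondition, float] | None = None
    for cond in candidates:
        fires = cond.evaluate(table)
        n_yes = int(fires.sum())
        n_no = len(y) - n_yes
        if n_yes < min_leaf or n_no < min_leaf or n_yes == 0 or n_no == 0:
            continue
        pos_y, neg_y = _weighted_counts(y[fires], class_weight)
        pos_n, neg_n = _weighted_counts(y[~fires], class_weight)
        child = (
            (pos_y + neg_y) * gini_impurity(pos_y, neg_y)
            + (pos_n + neg_n) * gini_impurity(pos_n, neg_n)
        ) / w_parent
        decrease = parent - child
        if best is None or decrease > best[1]:
            best = (cond, decrease)
    return best


def _leaf_risk(y: np.ndarray, class_weight: float) -> float:
    pos, neg = _weighted_counts(np.asarray(y), class_weight)
    return pos / (pos + neg)


def fit_cart_tree(
    cohort,
    outcome: np.ndarray | None = None,
    *,
    max_depth: int = 4,
    min_leaf: int = 10,
    class_weight: float = 5.0,
) -> DecisionTreeModel:
    """Greedy top-down CART growth with the (class-weighted) Gini criterion.

    Fully deterministic: no randomness enters the fit, so re-development
    under different seeds cannot change the model.
    """
    table = _as_table(cohort)
    y = np.asarray(outcome if outcome is not None else cohort.outcome, dtype=int)
    if y.min() == y.max():
        warnings.warn("single-class input: degenerate single-leaf tree")

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        sub_y = y[idx]
        if depth >= max_depth:
            return TreeNode(risk=_leaf_risk(sub_y, class_weight), n=len(idx))
        found = best_split(
            table.iloc[idx], sub_y, class_weight=class_weight, min_leaf=min_leaf
        )
        if found is None or found[1] <= 0:
            return TreeNode(risk=_leaf_risk(sub_y, class_weight), n=len(idx))
        cond, _ = found
        fires = cond.evaluate(table.iloc[idx])
        return TreeNode(
            condition=cond,
            yes=grow(idx[fires], depth + 1),
            no=grow(idx[~fires], depth + 1),
            n=len(idx),
        )

    root = grow(np.arange(len(table)), 0)
    return DecisionTreeModel(
        root,
        params={"max_depth": max_depth, "min_leaf": min_leaf, "class_weight": class_weight},
    )


def fit_cart_rule_list(
    cohort,
    outcome: np.ndarray | None = None,
    *,
    max_rules: int = MAX_LOGICAL_STEPS,
    min_leaf: int = 10,
    class_weight: float = 5.0,
) -> RuleList:
    """CART-style rule list by iterative one-sided partitioning.

    At each step the best Gini split of the remaining patients is found and
    the *higher-risk* side is peeled off as a leaf with its (class-weighted)
    empirical risk; the procedure recurses on the remainder, which becomes
    the default leaf.  Deterministic; stops at ``max_rules``, ``min_leaf``,
    purity, or when no admissible split exists.
    """
    if max_rules > MAX_LOGICAL_STEPS:
        raise ValueError("max_rules exceeds the interpretability cap")
    table = _as_table(cohort)
    y = np.asarray(outcome if outcome is not None else cohort.outcome, dtype=int)
    if y.min() == y.max():
        warnings.warn("single-class input: degenerate empty rule list")
    remaining = np.arange(len(table))
    conditions: list[RuleCondition] = []
    leaf_risks: list[float] = []
    while len(conditions) < max_rules:
        found = best_split(
            table.iloc[remaining],
            y[remaining],
            class_weight=class_weight,
            min_leaf=min_leaf,
        )
        if found is None or found[1] <= 0:
            break
        cond, _ = found
        fires = cond.evaluate(table.iloc[remaining])
        risk_yes = _leaf_risk(y[remaining[fires]], class_weight)
        risk_no = _leaf_risk(y[remaining[~fires]], class_weight)
        if risk_yes >= risk_no:
            conditions.append(cond)
            leaf_risks.append(risk_yes)
            remaining = remaining[~fires]
        else:
            conditions.append(cond.negate())
            leaf_risks.append(risk_no)
            remaining = remaining[fires]
        if len(remaining) == 0:
            break
    default = _leaf_risk(y[remaining], class_weight) if len(remaining) else 0.0
    return RuleList(
        conditions,
        leaf_risks,
        default,
        params={"max_rules": max_rules, "min_leaf": min_leaf, "class_weight": class_weight},
    )


# ---------------------------------------------------------------------------
# Rule ensemble (RuleFit-style, simplified)
# ---------------------------------------------------------------------------


def _rule_key(rule: list[RuleCondition]) -> tuple:
    return tuple(sorted((c.predictor, c.op, float(c.threshold)) for c in rule))


def _extract_paths(node: TreeNode, prefix: list[RuleCondition]) -> list[list[RuleCondition]]:
    if node.is_leaf:
        return []
    yes_rule = prefix + [node.condition]
    no_rule = prefix + [node.condition.negate()]
    out = [yes_rule, no_rule]
    out += _extract_paths(node.yes, yes_rule)
    out += _extract_paths(node.no, no_rule)
    return out


def _fit_logistic_irls(X: np.ndarray, y: np.ndarray, l2: float = 1e-3) -> np.ndarray:
    """L2-penalized logistic fit by L-BFGS; deterministic zero init."""
    n, p = X.shape
    Xb = np.hstack([np.ones((n, 1)), X])

    def loss(beta: np.ndarray):
        z = Xb @ beta
        ll = np.logaddexp(0.0, z) - y * z
        grad = Xb.T @ (expit(z) - y)
        pen = np.r_[0.0, beta[1:]]
        return ll.sum() + 0.5 * l2 * (pen @ pen), grad + l2 * pen

    res = minimize(loss, np.zeros(p + 1), jac=True, method="L-BFGS-B")
    return res.x


def fit_rule_ensemble(
    cohort,
    outcome: np.ndarray | None = None,
    *,
    n_trees: int = 30,
    tree_depth: int = 2,
    max_rules: int = 8,
    min_leaf: int = 10,
    class_weight: float = 5.0,
    w: float = 5.0,
    seed: int = 0,
) -> RuleEnsembleModel:
    """Mine conjunctive rules from bagged shallow CART trees, select sparsely.

    Candidate rules are every root-to-node path of ``n_trees`` bootstrap
    trees of depth <= ``tree_depth``, deduplicated, and kept only if their
    firing subgroup carries above-base-rate outcome risk (a screening rule
    assembles elevated-risk subgroups).  Rules are then added greedily
    while they improve the 5:1 sensitivity-weighted score of the
    OR-of-selected-rules classifier on the development data, up to
    ``max_rules``.  Risks come from an L2-penalized logistic fit on the
    selected rule activations.  Seedable and deterministic under a seed.
    """
    table = _as_table(cohort)
    y = np.asarray(outcome if outcome is not None else cohort.outcome, dtype=int)
    rng = np.random.default_rng(seed)
    seen: dict[tuple, list[RuleCondition]] = {}
    for _ in range(n_trees):
        boot = rng.integers(0, len(table), size=len(table))
        if y[boot].min() == y[boot].max():
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tree = fit_cart_tree(
                table.iloc[boot],
                y[boot],
                max_depth=tree_depth,
                min_leaf=min_leaf,
                class_weight=class_weight,
            )
        for rule in _extract_paths(tree.root, []):
            seen.setdefault(_rule_key(rule), rule)
    candidates = [seen[k] for k in sorted(seen)]
    if not candidates:
        warnings.warn("no candidate rules mined: intercept-only ensemble")
        base = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
        return RuleEnsembleModel([], [], float(np.log(base / (1 - base))))

    fire_mat = np.column_stack(
        [np.logical_and.reduce([c.evaluate(table) for c in rule]) for rule in candidates]
    )
    # screening rules assemble elevated-risk subgroups: a candidate whose
    # firing subgroup is at or below the cohort's base rate (e.g. a mined
    # complement path) is inadmissible, otherwise greedy OR-selection under
    # the sensitivity-weighted score degenerates to the all-positive rule
    base_rate = y.mean()
    admissible = [
        j
        for j in range(len(candidates))
        if fire_mat[:, j].any() and y[fire_mat[:, j]].mean() > base_rate
    ]
    candidates = [candidates[j] for j in admissible]
    fire_mat = fire_mat[:, admissible]
    if not candidates:
        warnings.warn("no elevated-risk candidate rules: intercept-only ensemble")
        base = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
        return RuleEnsembleModel([], [], float(np.log(base / (1 - base))),
                                 params={"seed": seed})
    n_pos = max(int(y.sum()), 1)
    n_neg = max(int(len(y) - y.sum()), 1)

    def score(mask: np.ndarray) -> float:
        sens = float((mask & (y == 1)).sum()) / n_pos
        spec = float((~mask & (y == 0)).sum()) / n_neg
        return (w * sens + spec) / (w + 1.0)

    selected: list[int] = []
    current = np.zeros(len(y), dtype=bool)
    current_score = score(current)
    while len(selected) < max_rules:
        best_j, best_s = None, current_score
        for j in range(len(candidates)):
            if j in selected:
                continue
            s = score(current | fire_mat[:, j])
            if s > best_s + 1e-12:
                best_j, best_s = j, s
        if best_j is None:
            break
        selected.append(best_j)
        current |= fire_mat[:, best_j]
        current_score = best_s

    if not selected:
        base = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
        return RuleEnsembleModel([], [], float(np.log(base / (1 - base))),
                                 params={"seed": seed})
    X = fire_mat[:, selected].astype(float)
    beta = _fit_logistic_irls(X, y.astype(float))
    return RuleEnsembleModel(
        [candidates[j] for j in selected],
        [float(b) for b in beta[1:]],
        float(beta[0]),
        params={
            "n_trees": n_trees,
            "tree_depth": tree_depth,
            "max_rules": max_rules,
            "min_leaf": min_leaf,
            "class_weight": class_weight,
            "seed": seed,
        },
    )


def fit_logistic(
    cohort,
    outcome: np.ndarray | None = None,
    *,
    l2: float = 1e-3,
) -> LogisticModel:
    table = _as_table(cohort)
    y = np.asarray(outcome if outcome is not None else cohort.outcome, dtype=float)
    X = table.to_numpy(dtype=float)
    beta = _fit_logistic_irls(X, y, l2=l2)
    return LogisticModel(
        list(table.columns), [float(b) for b in beta[1:]], float(beta[0]),
        params={"l2": l2},
    )


# ---------------------------------------------------------------------------
# Reference CDI
# ---------------------------------------------------------------------------

# Seven ordered findings of the PECARN-style reference rule; a patient is
# "very low risk" iff none fires.  Leaf risks decrease strictly down the
# list (the reference uses this package's synthetic calibration, since the
# original risks are published only graphically).
DEFAULT_REFERENCE_CONDITIONS: list[tuple[str, str, float]] = [
    ("abd_trauma_or_seatbelt_sign", "==", 1),
    ("gcs", "<", 14),
    ("abd_tenderness", "==", 1),
    ("thoracic_wall_trauma", "==", 1),
    ("abd_pain_complaint", "==", 1),
    ("decreased_breath_sounds", "==", 1),
    ("vomiting", "==", 1),
]
DEFAULT_REFERENCE_RISKS: list[float] = [0.080, 0.045, 0.022, 0.005, 0.0035, 0.002, 0.0007]
DEFAULT_REFERENCE_DEFAULT_RISK: float = 0.00008


def pecarn_reference_cdi(
    conditions: Sequence[tuple[str, str, float]] | None = None,
    leaf_risks: Sequence[float] | None = None,
    default_risk: float | None = None,
) -> RuleList:
    """The fixed, frozen seven-condition reference rule list."""
    conds = [RuleCondition(*c) for c in (conditions or DEFAULT_REFERENCE_CONDITIONS)]
    risks = list(leaf_risks if leaf_risks is not None else DEFAULT_REFERENCE_RISKS)
    default = DEFAULT_REFERENCE_DEFAULT_RISK if default_risk is None else default_risk
    return RuleList(conds, risks, default, provenance="reference")


def truncate_rule_list(rule_list: RuleList, k: int) -> RuleList:
    """First ``k`` conditions of a rule list, same default leaf."""
    return RuleList(
        rule_list.conditions[:k],
        rule_list.leaf_risks[:k],
        rule_list.default_risk,
        provenance=rule_list.provenance,
        params=dict(rule_list.params, truncated_to=k),
    )


# ---------------------------------------------------------------------------
# Refit randomness
# ---------------------------------------------------------------------------


@dataclass
class RefitSpread:
    """Stability of a fitter to its own randomness, over seeds 1..n."""

    score_spread: float
    risk_spread: float
    scores: list[float]


def refit_randomness(
    fitter: Callable[[int], Model],
    cohort,
    n_seeds: int = 10,
    *,
    w: float = 5.0,
) -> RefitSpread:
    """Refit with seeds 1..n_seeds; report max pairwise spread.

    ``score_spread`` is the max pairwise difference in the 5:1 weighted
    score at each refit's own operating point; ``risk_spread`` the max
    absolute elementwise difference between predicted-risk vectors.
    """
    from .diagnostics import select_operating_point, sens_spec_curve

    if n_seeds < 2:
        raise ValueError("n_seeds must be at least 2")
    y = np.asarray(cohort.outcome, dtype=int)
    scores, risk_mat = [], []
    for seed in range(1, n_seeds + 1):
        model = fitter(seed)
        risks = predict_risk(model, cohort)
        op = select_operating_point(sens_spec_curve(risks, y), w=w)
        scores.append(op.score)
        risk_mat.append(risks)
    risk_mat = np.asarray(risk_mat)
    return RefitSpread(
        score_spread=float(max(scores) - min(scores)),
        risk_spread=float((risk_mat.max(axis=0) - risk_mat.min(axis=0)).max()),
        scores=[float(s) for s in scores],
    )


# ---------------------------------------------------------------------------
# Serialization / rendering
# ---------------------------------------------------------------------------


def _cond_dict(c: RuleCondition) -> dict:
    return {"predictor": c.predictor, "op": c.op, "threshold": float(c.threshold)}


def _cond_from(d: dict) -> RuleCondition:
    return RuleCondition(d["predictor"], d["op"], d["threshold"])


def _tree_dict(node: TreeNode) -> dict:
    if node.is_leaf:
        return {"risk": node.risk, "n": node.n}
    return {
        "condition": _cond_dict(node.condition),
        "yes": _tree_dict(node.yes),
        "no": _tree_dict(node.no),
        "n": node.n,
    }


def _tree_from(d: dict) -> TreeNode:
    if "condition" not in d:
        return TreeNode(risk=d["risk"], n=d.get("n", 0))
    return TreeNode(
        condition=_cond_from(d["condition"]),
        yes=_tree_from(d["yes"]),
        no=_tree_from(d["no"]),
        n=d.get("n", 0),
    )


def model_to_json(model: Model) -> str:
    if isinstance(model, RuleList):
        payload = {
            "type": "rule_list",
            "conditions": [_cond_dict(c) for c in model.conditions],
            "leaf_risks": [float(r) for r in model.leaf_risks],
            "default_risk": float(model.default_risk),
        }
    elif isinstance(model, DecisionTreeModel):
        payload = {"type": "decision_tree", "root": _tree_dict(model.root)}
    elif isinstance(model, RuleEnsembleModel):
        payload = {
            "type": "rule_ensemble",
            "rules": [[_cond_dict(c) for c in rule] for rule in model.rules],
            "weights": [float(x) for x in model.weights],
            "intercept": float(model.intercept),
        }
    elif isinstance(model, LogisticModel):
        payload = {
            "type": "logistic",
            "predictors": model.predictors,
            "coef": [float(c) for c in model.coef],
            "intercept": float(model.intercept),
        }
    else:  # pragma: no cover
        raise TypeError(type(model))
    payload["provenance"] = model.provenance
    payload["params"] = model.params
    return json.dumps(payload, indent=2, sort_keys=True)


def model_from_json(text: str) -> Model:
    d = json.loads(text)
    kind = d["type"]
    if kind == "rule_list":
        return RuleList(
            [_cond_from(c) for c in d["conditions"]],
            d["leaf_risks"],
            d["default_risk"],
            provenance=d.get("provenance", "fitted"),
            params=d.get("params", {}),
        )
    if kind == "decision_tree":
        return DecisionTreeModel(
            _tree_from(d["root"]), d.get("provenance", "fitted"), d.get("params", {})
        )
    if kind == "rule_ensemble":
        return RuleEnsembleModel(
            [[_cond_from(c) for c in rule] for rule in d["rules"]],
            d["weights"],
            d["intercept"],
            d.get("provenance", "fitted"),
            d.get("params", {}),
        )
    if kind == "logistic":
        return LogisticModel(
            d["predictors"], d["coef"], d["intercept"],
            d.get("provenance", "fitted"), d.get("params", {}),
        )
    raise ValueError(f"unknown model type {kind!r}")


def render_text(model: Model) -> str:
    """Human-readable IF/ELSE rendering."""
    if isinstance(model, RuleList):
        lines = []
        for i, (cond, risk) in enumerate(zip(model.conditions, model.leaf_risks)):
            kw = "IF" if i == 0 else "ELIF"
            lines.append(f"{kw} {cond}: risk = {risk:.4f}")
        lines.append(f"ELSE: risk = {model.default_risk:.4f}")
        return "\n".join(lines)
    if isinstance(model, DecisionTreeModel):
        lines: list[str] = []

        def walk(node: TreeNode, indent: int) -> None:
            pad = "  " * indent
            if node.is_leaf:
                lines.append(f"{pad}risk = {node.risk:.4f} (n={node.n})")
                return
            lines.append(f"{pad}IF {node.condition}:")
            walk(node.yes, indent + 1)
            lines.append(f"{pad}ELSE:")
            walk(node.no, indent + 1)

        walk(model.root, 0)
        return "\n".join(lines)
    if isinstance(model, RuleEnsembleModel):
        lines = [f"intercept = {model.intercept:.4f}"]
        for rule, wt in zip(model.rules, model.weights):
            conj = " AND ".join(str(c) for c in rule)
            lines.append(f"{wt:+.4f} * [{conj}]")
        return "\n".join(lines)
    if isinstance(model, LogisticModel):
        lines = [f"intercept = {model.intercept:.4f}"]
        lines += [f"{c:+.4f} * {p}" for p, c in zip(model.predictors, model.coef)]
        return "\n".join(lines)
    raise TypeError(type(model))
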