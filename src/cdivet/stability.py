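"""Variable- and model-level stability analysis for candidate CDIs.

Variable-level stability asks how consistently a predictor matters across
the screened CDIs: its frequency (how many models structurally use it) and
its permutation importance (drop in the 5:1 sensitivity-weighted score
when the column is shuffled).  A predictor a model never references gets
an importance of exactly zero, without any shuffling.

Model-level stability asks how much a CDI's performance degrades from the
development to the validation data (a large drop suggests overfitting) and
how much its refit varies under fitting randomness.

CDIs are ranked lexicographically: validation weighted score (descending),
then performance drop (ascending), then refit spread (ascending).
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diagnostics import DiagnosticReport, weighted_score
from .rule_models import Model, RefitSpread, model_variables, predict_risk

__all__ = [
    "StabilityTable",
    "ModelStability",
    "permutation_importance",
    "variable_frequency",
    "build_stability_table",
    "variable_stability_rank",
    "performance_drop",
    "rank_cdis",
]


def _score_at(risks: np.ndarray, y: np.ndarray, threshold: float, w: float) -> float:
    pos = y == 1
    sens = float((risks[pos] >= threshold).mean()) if pos.any() else float("nan")
    spec = float((risks[~pos] < threshold).mean()) if (~pos).any() else float("nan")
    return weighted_score(sens, spec, w)


def permutation_importance(
    model: Model,
    cohort,
    threshold: float,
    *,
    w: float = 5.0,
    n_perm: int = 100,
    seed: int = 0,
) -> dict[str, float]:
    """Mean drop in weighted score after shuffling each predictor column.

    Shuffles happen within the evaluation cohort; each variable draws its
    permutations from a named substream of ``seed`` so results do not
    depend on column order.  Variables absent from the model's structure
    short-circuit to exactly 0.0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    table = cohort.predictors
    y = np.asarray(cohort.outcome, dtype=int)
    baseline = _score_at(predict_risk(model, table), y, threshold, w)
    used = set(model_variables(model))
    out: dict[str, float] = {}
    for col in table.columns:
        if col not in used:
            out[col] = 0.0
            continue
        digest = hashlib.sha256(col.encode()).digest()
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, int.from_bytes(digest[:8], "big")])
        )
        drops = []
        shuffled = table.copy()
        values = table[col].to_numpy()
        for _ in range(n_perm):
            shuffled[col] = values[rng.permutation(len(values))]
            drops.append(baseline - _score_at(predict_risk(model, shuffled), y, threshold, w))
        out[col] = float(np.mean(drops))
    return out


def variable_frequency(models: dict[str, Model], variables=None) -> dict[str, int]:
    """Count of models whose structure references each variable."""
    if not models:
        raise ValueError("need at least one model")
    if variables is None:
        variables = []
        for model in models.values():
            for v in model_variables(model):
                if v not in variables:
                    variables.append(v)
    counts = {v: 0 for v in variables}
    for model in models.values():
        used = set(model_variables(model))
        for v in variables:
            if v in used:
                counts[v] += 1
    return counts


@dataclass
class StabilityTable:
    """Per-variable frequency and per-(variable, model) permutation importance."""

    frequency: pd.Series  # index: variable
    importance: pd.DataFrame  # rows: variables, columns: models

    def to_frame(self) -> pd.DataFrame:
        out = self.importance.copy()
        out.insert(0, "frequency", self.frequency)
        return out

    def mean_nonzero_importance(self) -> pd.Series:
        def row_mean(row: pd.Series) -> float:
            nz = row[row != 0.0]
            return float(nz.mean()) if len(nz) else 0.0

        return self.importance.apply(row_mean, axis=1)


def build_stability_table(
    models: dict[str, Model],
    cohort,
    thresholds: dict[str, float],
    *,
    w: float = 5.0,
    n_perm: int = 100,
    seed: int = 0,
) -> StabilityTable:
    variables = list(cohort.predictors.columns)
    freq = variable_frequency(models, variables)
    importance = pd.DataFrame(index=variables, dtype=float)
    for name, model in models.items():
        imp = permutation_importance(
            model, cohort, thresholds[name], w=w, n_perm=n_perm, seed=seed
        )
        importance[name] = pd.Series(imp)
    return StabilityTable(pd.Series(freq, name="frequency"), importance)


def variable_stability_rank(table: StabilityTable) -> list[str]:
    """Order variables by frequency desc, mean non-zero importance desc, name asc."""
    mean_imp = table.mean_nonzero_importance()
    return sorted(
        table.frequency.index,
        key=lambda v: (-int(table.frequency[v]), -float(mean_imp[v]), v),
    )


@dataclass
class ModelStability:
    dev_score: float
    val_score: float
    drop: float
    refit_spread: float = 0.0

    @classmethod
    def from_reports(
        cls,
        dev_report: DiagnosticReport,
        val_report: DiagnosticReport,
        *,
        w: float = 5.0,
        refit: RefitSpread | None = None,
    ) -> "ModelStability":
        dev = weighted_score(dev_report.sensitivity, dev_report.specificity, w)
        val = weighted_score(val_report.sensitivity, val_report.specificity, w)
        return cls(dev, val, dev - val, 0.0 if refit is None else refit.score_spread)


def performance_drop(
    dev_report: DiagnosticReport,
    val_report: DiagnosticReport,
    *,
    w: float = 5.0,
    refit: RefitSpread | None = None,
) -> ModelStability:
    """Development-to-validation drop in the weighted score (may be negative)."""
    return ModelStability.from_reports(dev_report, val_report, w=w, refit=refit)


def rank_cdis(
    dev_reports: dict[str, DiagnosticReport],
    val_reports: dict[str, DiagnosticReport],
    stability: dict[str, ModelStability],
) -> list[dict]:
    """Total order over CDIs with all ranking keys logged.

    Primary key: validation weighted score (descending); secondary:
    development-to-validation drop (ascending); tertiary: refit spread
    (ascending); final tie-break: model name.  Invariant to input order.
    """
    names = set(dev_reports) | set(val_reports) | set(stability)
    if not (set(dev_reports) == set(val_reports) == set(stability) == names):
        raise ValueError("model sets differ between inputs")
    rows = [
        {
            "model": name,
            "val_score": stability[name].val_score,
            "dev_score": stability[name].dev_score,
            "drop": stability[name].drop,
            "refit_spread": stability[name].refit_spread,
        }
        for name in sorted(names)
    ]
    rows.sort(key=lambda r: (-r["val_score"], r["drop"], r["refit_spread"], r["model"]))
    for i, row in enumerate(rows):
        row["rank"] = i + 1
    return rows
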