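"""Cohort preprocessing: screening, imputation, merging, stratified split.

The pipeline order is fixed and mirrors the original derivation protocol:

1. drop any predictor missing in strictly more than 5% of patients;
2. drop any predictor whose inter-rater Cohen's kappa has a 95% CI lower
   bound below 0.4 (variables without duplicate ratings pass unscreened,
   but are logged);
3. impute remaining missing values with the column median (binary ties
   resolve to the more frequent value, exact ties to 0);
4. merge binary predictor pairs whose phi correlation reaches the
   redundancy threshold (default 0.95) into a logical-OR column;
5. split the cohort into development and validation sets, stratified on
   the outcome (default 66.3% development, reproducing a 7,985 / 4,059
   division of 12,044 patients).

Every removal or merge is recorded in a :class:`ScreenReport`.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.inter_rater import cohens_kappa

from .synth_cohort import Cohort

__all__ = [
    "ScreenReport",
    "SplitPair",
    "missingness_filter",
    "kappa_with_ci",
    "reliability_filter",
    "impute_median",
    "merge_redundant",
    "stratified_split",
    "apply_screen",
    "preprocess_cohort",
]


@dataclass
class ScreenReport:
    kept: list[str] = field(default_factory=list)
    dropped_missingness: list[tuple[str, float]] = field(default_factory=list)
    dropped_reliability: list[tuple[str, float, float, float]] = field(default_factory=list)
    unscreened_reliability: list[str] = field(default_factory=list)
    merges: list[tuple[str, list[str], float]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kept": self.kept,
                "dropped_missingness": [
                    {"name": n, "missing_fraction": f} for n, f in self.dropped_missingness
                ],
                "dropped_reliability": [
                    {"name": n, "kappa": k, "ci_low": lo, "ci_high": hi}
                    for n, k, lo, hi in self.dropped_reliability
                ],
                "unscreened_reliability": self.unscreened_reliability,
                "merges": [
                    {"name": n, "constituents": parts, "phi": phi}
                    for n, parts, phi in self.merges
                ],
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScreenReport":
        payload = json.loads(text)
        return cls(
            kept=list(payload.get("kept", [])),
            dropped_missingness=[
                (d["name"], d["missing_fraction"])
                for d in payload.get("dropped_missingness", [])
            ],
            dropped_reliability=[
                (d["name"], d["kappa"], d["ci_low"], d["ci_high"])
                for d in payload.get("dropped_reliability", [])
            ],
            unscreened_reliability=list(payload.get("unscreened_reliability", [])),
            merges=[
                (d["name"], list(d["constituents"]), d["phi"])
                for d in payload.get("merges", [])
            ],
        )


@dataclass
class SplitPair:
    development: Cohort
    validation: Cohort
    frac: float
    dev_indices: np.ndarray | None = None
    val_indices: np.ndarray | None = None

    def indices_frame(self) -> pd.DataFrame:
        """Fold assignment as a two-column (row_id, fold) table."""
        if self.dev_indices is None or self.val_indices is None:
            raise ValueError("split indices were not recorded")
        frame = pd.DataFrame(
            {
                "row_id": np.concatenate([self.dev_indices, self.val_indices]),
                "fold": ["development"] * len(self.dev_indices)
                + ["validation"] * len(self.val_indices),
            }
        )
        return frame.sort_values("row_id", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Screens
# ---------------------------------------------------------------------------


def missingness_filter(cohort: Cohort, max_frac: float = 0.05) -> tuple[Cohort, ScreenReport]:
    """Drop predictors missing in strictly more than ``max_frac`` of rows.

    The boundary is exclusive: a column missing exactly 5% is retained.
    The outcome is never screened.
    """
    if not (0.0 <= max_frac < 1.0):
        raise ValueError("max_frac must be in [0, 1)")
    report = ScreenReport()
    drop = []
    for col in cohort.predictors.columns:
        frac = float(cohort.predictors[col].isna().mean())
        if frac > max_frac:
            drop.append(col)
            report.dropped_missingness.append((col, frac))
        else:
            report.kept.append(col)
    out = cohort.copy()
    out.predictors = out.predictors.drop(columns=drop)
    if out.rater_b is not None:
        out.rater_b = out.rater_b.drop(columns=[c for c in drop if c in out.rater_b.columns])
    return out, report


def kappa_with_ci(ratings_a, ratings_b) -> tuple[float, float, float]:
    """Cohen's kappa with its asymptotic 95% CI for two binary raters.

    Returns (kappa, ci_low, ci_high); when expected agreement is 1 (both
    raters use a single category) kappa is undefined and NaNs are returned.
    """
    a = np.asarray(ratings_a, dtype=float)
    b = np.asarray(ratings_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("rating vectors differ in length")
    if len(a) < 2:
        raise ValueError("need at least two paired ratings")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("ratings must not contain missing values")
    for v in (a, b):
        if not np.isin(np.unique(v), (0.0, 1.0)).all():
            raise ValueError("ratings must be binary")
    table = np.array(
        [
            [np.sum((a == 1) & (b == 1)), np.sum((a == 1) & (b == 0))],
            [np.sum((a == 0) & (b == 1)), np.sum((a == 0) & (b == 0))],
        ],
        dtype=float,
    )
    n = table.sum()
    p_e = float((table.sum(1) / n) @ (table.sum(0) / n))
    if p_e >= 1.0 - 1e-12:
        return float("nan"), float("nan"), float("nan")
    res = cohens_kappa(table, return_results=True)
    return float(res.kappa), float(res.kappa_low), float(res.kappa_upp)


def reliability_filter(
    cohort: Cohort, min_ci_low: float = 0.4, report: ScreenReport | None = None
) -> tuple[Cohort, ScreenReport]:
    """Drop predictors whose kappa 95% CI lower bound is below ``min_ci_low``.

    Only binary predictors with a duplicate-rating column are screened;
    all others pass through and are logged as unscreened.  Kappa is
    computed on rows where the first rating is observed.
    """
    report = report if report is not None else ScreenReport(kept=list(cohort.predictors.columns))
    out = cohort.copy()
    drop = []
    for col in cohort.predictors.columns:
        values = cohort.predictors[col]
        observed = values.dropna()
        is_binary = np.isin(observed.unique(), (0.0, 1.0)).all()
        has_rater_b = cohort.rater_b is not None and col in cohort.rater_b.columns
        if not (is_binary and has_rater_b):
            report.unscreened_reliability.append(col)
            continue
        mask = values.notna() & cohort.rater_b[col].notna()
        kappa, lo, hi = kappa_with_ci(values[mask], cohort.rater_b[col][mask])
        if not np.isfinite(lo) or lo < min_ci_low:
            drop.append(col)
            report.dropped_reliability.append((col, kappa, lo, hi))
    out.predictors = out.predictors.drop(columns=drop)
    if out.rater_b is not None:
        out.rater_b = out.rater_b.drop(columns=[c for c in drop if c in out.rater_b.columns])
    report.kept = [c for c in report.kept if c not in drop]
    return out, report


# ---------------------------------------------------------------------------
# Imputation and redundancy merging
# ---------------------------------------------------------------------------


def _column_fill_value(values: pd.Series) -> float:
    observed = values.dropna().to_numpy(dtype=float)
    if len(observed) == 0:
        raise ValueError(f"column {values.name!r} is fully missing; drop it first")
    if np.isin(np.unique(observed), (0.0, 1.0)).all():
        n1 = int(observed.sum())
        n0 = len(observed) - n1
        return 1.0 if n1 > n0 else 0.0  # exact tie -> 0
    return float(np.percentile(observed, 50, method="nearest"))


def impute_median(cohort: Cohort) -> Cohort:
    """Replace missing entries with the column median of observed values."""
    out = cohort.copy()
    for col in out.predictors.columns:
        values = out.predictors[col]
        if values.isna().any():
            out.predictors[col] = values.fillna(_column_fill_value(values))
    return out


def _phi(x: np.ndarray, y: np.ndarray) -> float:
    """Phi coefficient of two binary vectors (Pearson r of 0/1 columns)."""
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def merge_redundant(
    cohort: Cohort, phi_threshold: float = 0.95, report: ScreenReport | None = None
) -> tuple[Cohort, ScreenReport]:
    """Merge binary pairs with |phi| >= threshold into a logical-OR column.

    Merge groups are the transitive closure of qualifying pairs; the merged
    column is named ``<a>_or_<b>`` in column order and placed at the first
    constituent's position.  Requires imputation to have run already.
    """
    if not (0.0 < phi_threshold <= 1.0):
        raise ValueError("phi threshold must be in (0, 1]")
    report = report if report is not None else ScreenReport(kept=list(cohort.predictors.columns))
    table = cohort.predictors
    if table.isna().any().any():
        raise ValueError("impute before merging redundant predictors")
    cols = list(table.columns)
    binary_cols = [
        c for c in cols if np.isin(table[c].unique(), (0.0, 1.0)).all()
    ]
    parent = {c: c for c in binary_cols}

    def find(c: str) -> str:
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    pair_phi: dict[frozenset, float] = {}
    for i, a in enumerate(binary_cols):
        xa = table[a].to_numpy(dtype=float)
        for b in binary_cols[i + 1:]:
            phi = _phi(xa, table[b].to_numpy(dtype=float))
            if abs(phi) >= phi_threshold:
                pair_phi[frozenset((a, b))] = phi
                parent[find(a)] = find(b)

    groups: dict[str, list[str]] = {}
    for c in binary_cols:
        groups.setdefault(find(c), []).append(c)
    out = cohort.copy()
    new_table = table.copy()
    for members in groups.values():
        if len(members) < 2:
            continue
        members = sorted(members, key=cols.index)
        name = "_or_".join(members)
        merged = new_table[members].max(axis=1)
        position = min(cols.index(m) for m in members)
        group_phis = [v for k, v in pair_phi.items() if k <= frozenset(members)]
        report.merges.append((name, members, float(max(group_phis))))
        new_table = new_table.drop(columns=members)
        insert_at = sum(
            1 for c in new_table.columns if cols.index(c) < position
        )
        new_table.insert(insert_at, name, merged)
        report.kept = [c for c in report.kept if c not in members]
        report.kept.append(name)
    out.predictors = new_table
    return out, report


# ---------------------------------------------------------------------------
# Stratified split
# ---------------------------------------------------------------------------


def stratified_split(cohort: Cohort, dev_frac: float = 0.663, seed: int = 0) -> SplitPair:
    """Outcome-stratified development/validation split.

    Each outcome class contributes round(dev_frac * n_class) patients to
    the development set, so prevalence differs between the halves by at
    most one count per stratum.  Reproducible under a fixed seed.
    """
    if not (0.0 < dev_frac < 1.0):
        raise ValueError("dev_frac must be in (0, 1)")
    y = cohort.outcome.to_numpy()
    rng = np.random.default_rng(seed)
    dev_idx: list[np.ndarray] = []
    for cls in (0, 1):
        members = np.flatnonzero(y == cls)
        if len(members) < 2:
            raise ValueError(f"outcome class {cls} has fewer than 2 members")
        take = int(round(dev_frac * len(members)))
        take = min(max(take, 1), len(members) - 1)
        dev_idx.append(rng.permutation(members)[:take])
    dev_mask = np.zeros(cohort.n, dtype=bool)
    dev_mask[np.concatenate(dev_idx)] = True

    def subset(mask: np.ndarray, label: str) -> Cohort:
        return Cohort(
            cohort.predictors.iloc[mask].reset_index(drop=True),
            cohort.outcome.iloc[mask].reset_index(drop=True),
            site=f"{cohort.site}:{label}",
            rater_b=None
            if cohort.rater_b is None
            else cohort.rater_b.iloc[mask].reset_index(drop=True),
        )

    return SplitPair(
        development=subset(dev_mask, "development"),
        validation=subset(~dev_mask, "validation"),
        frac=dev_frac,
        dev_indices=np.flatnonzero(dev_mask),
        val_indices=np.flatnonzero(~dev_mask),
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def apply_screen(cohort: Cohort, report: ScreenReport) -> Cohort:
    """Apply frozen screening decisions from another cohort to this one.

    Drops the columns the report dropped (where present), imputes medians,
    and rebuilds the report's merged OR-columns from their constituents.
    Used to carry development-time preprocessing onto an external cohort
    without re-deriving any decision from the external data.
    """
    out = cohort.copy()
    dropped = {n for n, _ in report.dropped_missingness}
    dropped |= {n for n, *_ in report.dropped_reliability}
    out.predictors = out.predictors.drop(
        columns=[c for c in dropped if c in out.predictors.columns]
    )
    out = impute_median(out)
    for name, members, _ in report.merges:
        present = [m for m in members if m in out.predictors.columns]
        if len(present) != len(members):
            continue  # constituents unavailable at this site; leave unmerged
        position = min(out.predictors.columns.get_loc(m) for m in present)
        merged = out.predictors[present].max(axis=1)
        out.predictors = out.predictors.drop(columns=present)
        out.predictors.insert(min(position, len(out.predictors.columns)), name, merged)
    return out


def preprocess_cohort(
    cohort: Cohort,
    max_missing: float = 0.05,
    min_kappa_ci_low: float = 0.4,
    phi_threshold: float = 0.95,
) -> tuple[Cohort, ScreenReport]:
    """Missingness filter -> reliability filter -> imputation -> merging.

    Idempotent: running the pipeline on its own output changes nothing.
    """
    out, report = missingness_filter(cohort, max_missing)
    out, report = reliability_filter(out, min_kappa_ci_low, report)
    out = impute_median(out)
    out, report = merge_redundant(out, phi_threshold, report)
    return out, report
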