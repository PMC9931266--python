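"""Diagnostic test characteristics for CDI screening and comparison.

Implements the full metric battery reported for each CDI (sensitivity,
specificity, NPV, PPV, likelihood ratios, F1, accuracy, Brier score),
threshold-free sensitivity-specificity curves, the 5:1
sensitivity-weighted score used to rank CDIs, operating-point selection
under a sensitivity floor, and the elimination screen (development
sensitivity below 90% removes a CDI from further analysis).

Classification convention: at threshold t a patient is called positive
("not very low risk") iff predicted risk >= t.  Ratios with a zero
denominator are reported as infinity with an explicit flag rather than
clamped.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "DiagnosticReport",
    "SensSpecCurve",
    "OperatingPoint",
    "confusion",
    "diagnostic_report",
    "report_at_threshold",
    "sens_spec_curve",
    "weighted_score",
    "select_operating_point",
    "screen_cdis",
    "format_percent",
    "format_brier",
    "reports_to_frame",
    "render_reports_markdown",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn


def confusion(outcome, predicted_positive) -> ConfusionCounts:
    """Exact 2x2 tally; 'positive' means the CDI fires (not very low risk)."""
    y = np.asarray(outcome, dtype=int)
    p = np.asarray(predicted_positive, dtype=int)
    if y.shape != p.shape:
        raise ValueError("outcome and prediction lengths differ")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


@dataclass
class DiagnosticReport:
    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    npv: float
    ppv: float
    lr_pos: float
    lr_neg: float
    f1: float
    accuracy: float
    brier: float
    threshold: float | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "tn": self.counts.tn,
            "fn": self.counts.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "npv": self.npv,
            "ppv": self.ppv,
            "lr_pos": self.lr_pos,
            "lr_neg": self.lr_neg,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "brier": self.brier,
            "threshold": self.threshold,
            "flags": list(self.flags),
        }


def _ratio(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(f"{name}_undefined")
        return float("nan") if num == 0 else float("inf")
    return num / den


def diagnostic_report(
    counts: ConfusionCounts,
    risks=None,
    outcome=None,
    threshold: float | None = None,
) -> DiagnosticReport:
    """Full metric battery from confusion counts (+ Brier from risks).

    ``risks``/``outcome`` are optional; without them the Brier score is NaN
    and flagged.  When both are given the counts must be consistent with
    the outcome vector.
    """
    if counts.n == 0:
        raise ValueError("empty input")
    flags: list[str] = []
    sens = _ratio(counts.tp, counts.positives, "sensitivity", flags)
    spec = _ratio(counts.tn, counts.negatives, "specificity", flags)
    npv = _ratio(counts.tn, counts.tn + counts.fn, "npv", flags)
    ppv = _ratio(counts.tp, counts.tp + counts.fp, "ppv", flags)
    lr_pos = _ratio(sens, 1.0 - spec, "lr_pos", flags)
    lr_neg = _ratio(1.0 - sens, spec, "lr_neg", flags)
    f1 = _ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn, "f1", flags)
    accuracy = (counts.tp + counts.tn) / counts.n
    if risks is not None and outcome is not None:
        y = np.asarray(outcome, dtype=float)
        r = np.asarray(risks, dtype=float)
        if len(y) != counts.n or int(y.sum()) != counts.positives:
            raise ValueError("counts inconsistent with outcome vector")
        brier = float(np.mean((r - y) ** 2))
    else:
        brier = float("nan")
        flags.append("brier_unavailable")
    return DiagnosticReport(
        counts, sens, spec, npv, ppv, lr_pos, lr_neg, f1, accuracy, brier,
        threshold=threshold, flags=flags,
    )


def report_at_threshold(risks, outcome, threshold: float) -> DiagnosticReport:
    """Classify at ``risk >= threshold`` and compute the full battery."""
    r = np.asarray(risks, dtype=float)
    y = np.asarray(outcome, dtype=int)
    counts = confusion(y, r >= threshold)
    return diagnostic_report(counts, r, y, threshold=threshold)


@dataclass
class SensSpecCurve:
    """Ordered (threshold, sensitivity, specificity) triples.

    One point per distinct predicted risk (classifying positive iff
    risk >= threshold) plus an all-negative sentinel at +inf; thresholds
    strictly increase, sensitivity is non-increasing and specificity
    non-decreasing along the curve.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray

    def __len__(self) -> int:
        return len(self.thresholds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def sens_spec_curve(risks, outcome) -> SensSpecCurve:
    y = np.asarray(outcome, dtype=int)
    r = np.asarray(risks, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("curve needs at least one positive and one negative")
    thresholds = np.append(np.unique(r), np.inf)
    # cumulative tallies: positives/negatives with risk >= t
    order = np.argsort(r, kind="stable")
    r_sorted = r[order]
    y_sorted = y[order]
    pos_below = np.searchsorted(r_sorted, thresholds, side="left")
    cum_pos = np.concatenate([[0], np.cumsum(y_sorted)])
    tp = n_pos - cum_pos[pos_below]
    fp = (len(y) - pos_below) - tp
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    return SensSpecCurve(thresholds, sens, spec)


def weighted_score(sensitivity: float, specificity: float, w: float = 5.0) -> float:
    """(w * sensitivity + specificity) / (w + 1); default weights sensitivity 5:1."""
    if w <= 0:
        raise ValueError("w must be positive")
    return (w * sensitivity + specificity) / (w + 1.0)


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    score: float
    floor_met: bool


def select_operating_point(
    curve: SensSpecCurve, w: float = 5.0, sens_floor: float = 0.95
) -> OperatingPoint:
    """Best weighted-score point with sensitivity >= the floor.

    If no point meets the floor, the maximum-sensitivity point is returned
    flagged ``floor_met=False``.  Ties go to the lower threshold (the
    higher-sensitivity side).
    """
    if len(curve) == 0:
        raise ValueError("empty curve")
    eligible = curve.sensitivity >= sens_floor
    if eligible.any():
        idx = np.flatnonzero(eligible)
        scores = weighted_score(curve.sensitivity[idx], curve.specificity[idx], w)
        best = idx[int(np.argmax(scores))]  # argmax takes first -> lower threshold
        floor_met = True
    else:
        best = int(np.argmax(curve.sensitivity))
        floor_met = False
    return OperatingPoint(
        threshold=float(curve.thresholds[best]),
        sensitivity=float(curve.sensitivity[best]),
        specificity=float(curve.specificity[best]),
        score=float(
            weighted_score(curve.sensitivity[best], curve.specificity[best], w)
        ),
        floor_met=floor_met,
    )


def screen_cdis(reports: dict[str, DiagnosticReport], min_sens: float = 0.90) -> list[str]:
    """Keep CDIs whose development operating sensitivity is >= the screen floor."""
    return [name for name, rep in reports.items() if rep.sensitivity >= min_sens]


# ---------------------------------------------------------------------------
# Rendering (percentages to 1 d.p., Brier to 3 d.p.)
# ---------------------------------------------------------------------------


def format_percent(x: float) -> str:
    if not np.isfinite(x):
        return "--"
    return f"{100 * x:.1f}%"


def format_brier(x: float) -> str:
    if not np.isfinite(x):
        return "--"
    return f"{x:.3f}"


_PERCENT_FIELDS = ("sensitivity", "specificity", "npv", "ppv", "accuracy")


def reports_to_frame(reports: dict[str, DiagnosticReport], formatted: bool = True) -> pd.DataFrame:
    """Models x metrics matrix in the reported-table style."""
    rows = {}
    for name, rep in reports.items():
        d = rep.to_dict()
        d.pop("flags")
        if formatted:
            for k in _PERCENT_FIELDS:
                d[k] = format_percent(d[k])
            d["brier"] = format_brier(d["brier"])
            for k in ("lr_pos", "lr_neg", "f1"):
                d[k] = "--" if not np.isfinite(d[k]) else f"{d[k]:.2f}"
        rows[name] = d
    return pd.DataFrame(rows).T


def render_reports_markdown(reports: dict[str, DiagnosticReport]) -> str:
    frame = reports_to_frame(reports, formatted=True)
    header = ["model"] + [str(c) for c in frame.columns]
    lines = ["| " + " | ".join(header) + " |",
             "|" + "|".join(["---"] * len(header)) + "|"]
    for name, row in frame.iterrows():
        lines.append("| " + " | ".join([str(name)] + [str(v) for v in row]) + " |")
    return "\n".join(lines)
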