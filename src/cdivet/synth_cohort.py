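"""Synthetic blunt-torso-trauma cohorts for exercising the vetting pipeline.

The real development (N=12,044, outcome prevalence 1.7%) and external
validation (N=2,188, prevalence 2.8%) cohorts are not publicly deposited,
so this module generates cohorts with the same statistical skeleton:

* named binary findings at configurable prevalences (motor-vehicle
  collision 31.8% internally vs 46.3% externally, etc.);
* an ordinal Glasgow Coma Scale (support 3..15, mass concentrated at 15);
* a binary outcome (intra-abdominal injury undergoing acute intervention)
  drawn from an embedded ordered true rule list whose leaf risks decrease
  strictly down the list;
* completely-at-random missingness per column, injected after the outcome;
* redundant predictor pairs at a target phi correlation (parent Bernoulli,
  child flipped with the closed-form probability that achieves the target);
* an optional second-rater table with imperfect agreement at a target
  Cohen's kappa (second rating equals the first with probability kappa,
  otherwise an independent redraw at the realized prevalence).

Randomness: a single integer master seed; every column draws from its own
substream derived from the seed and the column name, so results do not
depend on column order.
"""
from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .rule_models import RuleCondition

__all__ = [
    "PredictorSpec",
    "TrueRuleConfig",
    "GeneratorConfig",
    "Cohort",
    "generate_cohort",
    "generate_rater_pair",
    "shift_site",
    "implied_prevalence",
    "pecarn_like_config",
    "pedsrc_like_config",
    "write_cohort_csv",
    "read_cohort_csv",
    "config_to_yaml",
    "config_from_yaml",
]

RATER_B_SUFFIX = "__rater_b"


def _rng_for(seed: int, *tokens) -> np.random.Generator:
    """Deterministic per-purpose substream, independent of column order."""
    digest = hashlib.sha256(":".join(map(str, tokens)).encode()).digest()
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int.from_bytes(digest[:8], "big")])
    )


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------


@dataclass
class PredictorSpec:
    """Marginal law of one predictor column.

    ``prevalence`` is the Bernoulli parameter for binary predictors; ordinal
    predictors instead carry a ``support``/``probs`` pair (category
    probabilities over the ordinal support, e.g. GCS 3..15).
    """

    name: str
    kind: str  # "binary" | "ordinal"
    prevalence: float | None = None
    support: list[int] | None = None
    probs: list[float] | None = None
    missing_rate: float = 0.0
    redundant_with: str | None = None
    redundant_phi: float | None = None
    rater_kappa: float | None = None

    def validate(self) -> None:
        if self.kind not in ("binary", "ordinal"):
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError(f"{self.name}: missing_rate must be in [0, 1)")
        if self.kind == "binary":
            if self.prevalence is None or not (0.0 <= self.prevalence <= 1.0):
                raise ValueError(f"{self.name}: binary prevalence must be in [0, 1]")
        else:
            if self.support is None or self.probs is None:
                raise ValueError(f"{self.name}: ordinal spec needs support and probs")
            if len(self.support) != len(self.probs):
                raise ValueError(f"{self.name}: support/probs length mismatch")
            if abs(sum(self.probs) - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: category probabilities must sum to 1")
            if self.redundant_with is not None or self.rater_kappa is not None:
                raise ValueError(
                    f"{self.name}: redundancy and rater agreement are binary-only"
                )
        if (self.redundant_with is None) != (self.redundant_phi is None):
            raise ValueError(f"{self.name}: redundant_with and redundant_phi go together")
        if self.redundant_phi is not None and not (-1.0 <= self.redundant_phi <= 1.0):
            raise ValueError(f"{self.name}: target phi must be in [-1, 1]")
        if self.rater_kappa is not None and not (0.0 <= self.rater_kappa <= 1.0):
            raise ValueError(f"{self.name}: rater kappa must be in [0, 1]")


@dataclass
class TrueRuleConfig:
    """The embedded ground-truth rule list generating the outcome."""

    conditions: list[RuleCondition]
    leaf_risks: list[float]
    default_risk: float

    def validate(self, predictor_names: set[str]) -> None:
        if len(self.conditions) != len(self.leaf_risks):
            raise ValueError("true rule: conditions/leaf_risks length mismatch")
        risks = list(self.leaf_risks) + [self.default_risk]
        if any(not (0.0 <= r <= 1.0) for r in risks):
            raise ValueError("true rule: risks must lie in [0, 1]")
        if any(b >= a for a, b in zip(self.leaf_risks, self.leaf_risks[1:])):
            raise ValueError("true rule: leaf risks must strictly decrease")
        if self.leaf_risks and self.default_risk >= self.leaf_risks[-1]:
            raise ValueError("true rule: default risk must be below the last leaf")
        for cond in self.conditions:
            if cond.predictor not in predictor_names:
                raise KeyError(f"true rule references unknown predictor {cond.predictor!r}")


@dataclass
class GeneratorConfig:
    predictors: list[PredictorSpec]
    true_rule: TrueRuleConfig
    n: int
    seed: int
    site_label: str = "cohort"

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        names = [p.name for p in self.predictors]
        if len(set(names)) != len(names):
            raise ValueError("predictor names must be unique")
        by_name = {p.name: p for p in self.predictors}
        for p in self.predictors:
            p.validate()
            if p.redundant_with is not None:
                if p.redundant_with not in by_name:
                    raise KeyError(f"{p.name}: redundant_with unknown predictor")
                # acyclicity: walk the parent chain
                seen = {p.name}
                cur = p.redundant_with
                while cur is not None:
                    if cur in seen:
                        raise ValueError(f"{p.name}: redundancy cycle detected")
                    seen.add(cur)
                    cur = by_name[cur].redundant_with
                if by_name[p.redundant_with].kind != "binary":
                    raise ValueError(f"{p.name}: redundancy parent must be binary")
        self.true_rule.validate(set(names))


@dataclass
class Cohort:
    """Predictor table + binary outcome; the unit every pipeline stage consumes."""

    predictors: pd.DataFrame
    outcome: pd.Series
    site: str = "cohort"
    rater_b: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.predictors) != len(self.outcome):
            raise ValueError("predictor table and outcome row counts differ")
        if self.outcome.isna().any():
            raise ValueError("outcome must have no missing values")
        if self.rater_b is not None and len(self.rater_b) != len(self.predictors):
            raise ValueError("rater-B table row count differs")
        if len(set(self.predictors.columns)) != len(self.predictors.columns):
            raise ValueError("duplicate predictor column names")

    @property
    def n(self) -> int:
        return len(self.predictors)

    @property
    def prevalence(self) -> float:
        return float(self.outcome.mean())

    def copy(self) -> "Cohort":
        return Cohort(
            self.predictors.copy(),
            self.outcome.copy(),
            self.site,
            None if self.rater_b is None else self.rater_b.copy(),
        )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _redundant_child(
    parent: np.ndarray, p: float, q: float, phi: float, rng: np.random.Generator
) -> np.ndarray:
    """Child Bernoulli(q) with target phi against a Bernoulli(p) parent.

    Closed form: P(child=1, parent=1) = phi * sqrt(p(1-p)q(1-q)) + p*q, so
    P(child=1 | parent=1) = p11/p and P(child=1 | parent=0) = (q-p11)/(1-p).
    """
    p11 = phi * np.sqrt(p * (1 - p) * q * (1 - q)) + p * q
    if p in (0.0, 1.0):
        raise ValueError("redundancy parent prevalence must be in (0, 1)")
    a = p11 / p
    b = (q - p11) / (1 - p)
    tol = 1e-9
    if not (-tol <= a <= 1.0 + tol and -tol <= b <= 1.0 + tol):
        raise ValueError("target phi unreachable at these prevalences")
    a, b = float(np.clip(a, 0.0, 1.0)), float(np.clip(b, 0.0, 1.0))
    u = rng.random(len(parent))
    return np.where(parent == 1, u < a, u < b).astype(float)


def _assign_risks(table: pd.DataFrame, rule: TrueRuleConfig) -> np.ndarray:
    """Per-patient true risk: first matching condition's leaf, else default."""
    risks = np.full(len(table), rule.default_risk, dtype=float)
    unmatched = np.ones(len(table), dtype=bool)
    for cond, risk in zip(rule.conditions, rule.leaf_risks):
        fires = cond.evaluate(table) & unmatched
        risks[fires] = risk
        unmatched &= ~fires
    return risks


def _generate_complete_table(config: GeneratorConfig, seed: int) -> pd.DataFrame:
    """All predictor columns, pre-missingness, in config order."""
    n = config.n
    cols: dict[str, np.ndarray] = {}
    # parents first so redundant children can condition on them
    for spec in config.predictors:
        if spec.redundant_with is not None:
            continue
        rng = _rng_for(seed, "col", spec.name)
        if spec.kind == "binary":
            cols[spec.name] = (rng.random(n) < spec.prevalence).astype(float)
        else:
            cols[spec.name] = rng.choice(
                np.asarray(spec.support, dtype=float), size=n, p=spec.probs
            )
    by_name = {p.name: p for p in config.predictors}
    # children in dependency order (chains are acyclic; iterate to fixpoint)
    pending = [p for p in config.predictors if p.redundant_with is not None]
    while pending:
        progressed = False
        for spec in list(pending):
            if spec.redundant_with in cols:
                rng = _rng_for(seed, "col", spec.name)
                parent_spec = by_name[spec.redundant_with]
                q = spec.prevalence if spec.prevalence is not None else parent_spec.prevalence
                cols[spec.name] = _redundant_child(
                    cols[spec.redundant_with],
                    parent_spec.prevalence,
                    q,
                    spec.redundant_phi,
                    rng,
                )
                pending.remove(spec)
                progressed = True
        if not progressed:  # pragma: no cover - guarded by validate()
            raise ValueError("unresolvable redundancy chain")
    return pd.DataFrame({p.name: cols[p.name] for p in config.predictors})


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a cohort from the configured joint law; bitwise reproducible.

    The outcome is assigned per patient as Bernoulli of the first matching
    true-rule condition's leaf risk (default risk if none matches), using
    the complete pre-missingness predictor values; missingness is injected
    completely at random per column afterwards.
    """
    config.validate()
    prev = implied_prevalence(config)
    if prev <= 0.0 or prev >= 1.0:
        raise ValueError("configuration implies a degenerate outcome prevalence")
    table = _generate_complete_table(config, config.seed)
    risks = _assign_risks(table, config.true_rule)
    outcome_rng = _rng_for(config.seed, "outcome")
    outcome = (outcome_rng.random(config.n) < risks).astype(int)

    # second-rater columns, drawn from the complete values
    rater_cols: dict[str, np.ndarray] = {}
    for spec in config.predictors:
        if spec.rater_kappa is not None:
            rater_cols[spec.name] = _rater_column(
                table[spec.name].to_numpy(),
                spec.rater_kappa,
                _rng_for(config.seed, "rater", spec.name),
            )
    rater_b = pd.DataFrame(rater_cols) if rater_cols else None

    # MCAR missingness, after outcome assignment
    for spec in config.predictors:
        if spec.missing_rate > 0:
            rng = _rng_for(config.seed, "missing", spec.name)
            mask = rng.random(config.n) < spec.missing_rate
            table.loc[mask, spec.name] = np.nan

    return Cohort(
        table,
        pd.Series(outcome, name="outcome"),
        site=config.site_label,
        rater_b=rater_b,
    )


def _rater_column(values: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Second rating agreeing at target kappa.

    B equals A with probability kappa; otherwise B is an independent
    Bernoulli at A's realized prevalence.  Then p_o = k + (1-k) p_e, so the
    expected Cohen's kappa is exactly the target, with symmetric
    disagreements.
    """
    p = float(values.mean())
    agree = rng.random(len(values)) < kappa
    fresh = (rng.random(len(values)) < p).astype(float)
    return np.where(agree, values, fresh)


def generate_rater_pair(
    cohort: Cohort, kappa_targets: dict[str, float], seed: int
) -> Cohort:
    """Fill the rater-B table for the listed binary variables."""
    out = cohort.copy()
    cols: dict[str, np.ndarray] = {} if out.rater_b is None else {
        c: out.rater_b[c].to_numpy() for c in out.rater_b.columns
    }
    for name, kappa in kappa_targets.items():
        if name not in cohort.predictors.columns:
            raise KeyError(name)
        if not (0.0 <= kappa <= 1.0):
            raise ValueError(f"{name}: kappa target must be in [0, 1]")
        col = cohort.predictors[name].to_numpy(dtype=float)
        observed = col[~np.isnan(col)]
        if not np.isin(np.unique(observed), (0.0, 1.0)).all():
            raise ValueError(f"{name}: rater agreement is supported for binary variables only")
        filled = np.where(np.isnan(col), 0.0, col)  # rate on observed values
        rated = _rater_column(filled, kappa, _rng_for(seed, "rater", name))
        rated[np.isnan(col)] = np.nan
        cols[name] = rated
    out.rater_b = pd.DataFrame(cols, index=cohort.predictors.index)
    return out


# ---------------------------------------------------------------------------
# Implied prevalence and site shift
# ---------------------------------------------------------------------------


def implied_prevalence(config: GeneratorConfig, n_mc: int = 200_000, seed: int = 12345) -> float:
    """Analytic outcome prevalence E[risk] by Monte-Carlo over the predictor law.

    Averages the assigned true-rule risk (not Bernoulli draws), so the
    Monte-Carlo error is far below binomial sampling error.
    """
    mc = replace(copy.deepcopy(config), n=n_mc, seed=seed)
    for p in mc.predictors:
        p.missing_rate = 0.0
    table = _generate_complete_table(mc, seed)
    return float(_assign_risks(table, mc.true_rule).mean())


def shift_site(
    config: GeneratorConfig,
    prevalence: dict[str, float] | None = None,
    risk_scale: float | None = None,
    target_prevalence: float | None = None,
    n: int | None = None,
    seed: int | None = None,
    site_label: str | None = None,
) -> GeneratorConfig:
    """New config with shifted marginals and/or uniformly scaled leaf risks.

    ``target_prevalence`` solves the uniform risk scale so the implied
    outcome prevalence hits the target (prevalence is linear in the scale).
    The input config is left unchanged.
    """
    out = copy.deepcopy(config)
    by_name = {p.name: p for p in out.predictors}
    for name, value in (prevalence or {}).items():
        if name not in by_name:
            raise KeyError(f"override references unknown predictor {name!r}")
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"{name}: overridden prevalence outside [0, 1]")
        if by_name[name].kind != "binary":
            raise ValueError(f"{name}: prevalence override is binary-only")
        by_name[name].prevalence = value
    if risk_scale is not None and target_prevalence is not None:
        raise ValueError("give either risk_scale or target_prevalence, not both")
    if target_prevalence is not None:
        base = implied_prevalence(out)
        risk_scale = target_prevalence / base
    if risk_scale is not None:
        scaled = [r * risk_scale for r in out.true_rule.leaf_risks]
        default = out.true_rule.default_risk * risk_scale
        if any(r > 1.0 for r in scaled) or default > 1.0:
            raise ValueError("risk scale pushes a leaf risk above 1")
        out.true_rule.leaf_risks = scaled
        out.true_rule.default_risk = default
    if n is not None:
        out.n = n
    if seed is not None:
        out.seed = seed
    if site_label is not None:
        out.site_label = site_label
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Default study configurations
# ---------------------------------------------------------------------------

# GCS pmf over 3..15: mass concentrated at 15, P(GCS < 14) = 0.08
_GCS_SUPPORT = list(range(3, 16))
_GCS_PROBS = [
    0.002, 0.002, 0.002, 0.003, 0.004, 0.004, 0.005,
    0.006, 0.008, 0.014, 0.030, 0.12, 0.80,
]

_STRONG_PREDICTORS = ("abd_trauma_or_seatbelt_sign", "gcs", "abd_tenderness")
_WEAK_PREDICTORS = (
    "thoracic_wall_trauma",
    "abd_pain_complaint",
    "decreased_breath_sounds",
    "vomiting",
)


def pecarn_like_config(n: int = 12_044, seed: int = 0) -> GeneratorConfig:
    """Development-site default: ~1.7% outcome prevalence, MVC 31.8%.

    Embeds a 7-condition true rule (3 strong conditions with large risk
    steps, then 4 weak ones with small increments), a redundant noise pair,
    a high-missingness column and a low-agreement column so every
    preprocessing screen has something to act on.
    """
    predictors = [
        PredictorSpec("abd_trauma_or_seatbelt_sign", "binary", 0.10,
                      missing_rate=0.01, rater_kappa=0.85),
        PredictorSpec("gcs", "ordinal", support=_GCS_SUPPORT, probs=_GCS_PROBS,
                      missing_rate=0.02),
        PredictorSpec("abd_tenderness", "binary", 0.25,
                      missing_rate=0.02, rater_kappa=0.80),
        PredictorSpec("thoracic_wall_trauma", "binary", 0.20,
                      missing_rate=0.02, rater_kappa=0.75),
        PredictorSpec("abd_pain_complaint", "binary", 0.25,
                      missing_rate=0.03, rater_kappa=0.70),
        PredictorSpec("decreased_breath_sounds", "binary", 0.12,
                      missing_rate=0.02, rater_kappa=0.75),
        PredictorSpec("vomiting", "binary", 0.15,
                      missing_rate=0.02, rater_kappa=0.80),
        PredictorSpec("mvc", "binary", 0.318, missing_rate=0.01),
        PredictorSpec("age_lt_2", "binary", 0.097),
        PredictorSpec("sex_male", "binary", 0.613),
        # exercises the >5% missingness screen
        PredictorSpec("distracting_injury", "binary", 0.12, missing_rate=0.08),
        # exercises the kappa CI lower-bound screen
        PredictorSpec("hypotension", "binary", 0.05, rater_kappa=0.25),
        # exercises redundancy merging (phi above the 0.95 default)
        PredictorSpec("femur_fracture", "binary", 0.07, missing_rate=0.01),
        PredictorSpec("thigh_deformity", "binary", 0.07, missing_rate=0.01,
                      redundant_with="femur_fracture", redundant_phi=0.98),
    ]
    rule = TrueRuleConfig(
        conditions=[
            RuleCondition("abd_trauma_or_seatbelt_sign", "==", 1),
            RuleCondition("gcs", "<", 14),
            RuleCondition("abd_tenderness", "==", 1),
            RuleCondition("thoracic_wall_trauma", "==", 1),
            RuleCondition("abd_pain_complaint", "==", 1),
            RuleCondition("decreased_breath_sounds", "==", 1),
            RuleCondition("vomiting", "==", 1),
        ],
        leaf_risks=[0.080, 0.045, 0.022, 0.005, 0.0035, 0.002, 0.0007],
        default_risk=0.00008,
    )
    return GeneratorConfig(predictors, rule, n=n, seed=seed, site_label="development")


def pedsrc_like_config(
    base: GeneratorConfig | None = None, n: int = 2_188, seed: int | None = None
) -> GeneratorConfig:
    """External-site default: covariate + prevalence shift, no sex column.

    MVC prevalence rises to 46.3% and leaf risks are scaled uniformly so the
    implied outcome prevalence is 2.8%; the ``sex_male`` column is absent
    (it has no counterpart at the external site, mirroring a one-sided
    schema mismatch).
    """
    base = base if base is not None else pecarn_like_config()
    out = shift_site(
        base,
        prevalence={"mvc": 0.463},
        target_prevalence=0.028,
        n=n,
        seed=base.seed + 1 if seed is None else seed,
        site_label="external",
    )
    out.predictors = [p for p in out.predictors if p.name != "sex_male"]
    out.validate()
    return out


def strong_predictors() -> tuple[str, ...]:
    """Names of the three embedded strong (recoverable) predictors."""
    return _STRONG_PREDICTORS


def weak_predictors() -> tuple[str, ...]:
    return _WEAK_PREDICTORS


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_cohort_csv(cohort: Cohort, path: str | Path, meta_path: str | Path | None = None) -> None:
    """CSV with header row, empty fields for missing values, sidecar JSON metadata."""
    path = Path(path)
    table = cohort.predictors.copy()
    table["outcome"] = cohort.outcome.to_numpy()
    if cohort.rater_b is not None:
        for col in cohort.rater_b.columns:
            table[col + RATER_B_SUFFIX] = cohort.rater_b[col].to_numpy()
    table.to_csv(path, index=False, na_rep="")
    meta = {
        "site_label": cohort.site,
        "n": cohort.n,
        "predictors": list(cohort.predictors.columns),
        "rater_b": [] if cohort.rater_b is None else list(cohort.rater_b.columns),
    }
    meta_path = Path(meta_path) if meta_path else path.with_suffix(".meta.json")
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_cohort_csv(path: str | Path, meta_path: str | Path | None = None) -> Cohort:
    path = Path(path)
    table = pd.read_csv(path)
    meta_path = Path(meta_path) if meta_path else path.with_suffix(".meta.json")
    site = "cohort"
    if meta_path.exists():
        site = json.loads(meta_path.read_text()).get("site_label", "cohort")
    outcome = table.pop("outcome").astype(int)
    rater_cols = [c for c in table.columns if c.endswith(RATER_B_SUFFIX)]
    rater_b = None
    if rater_cols:
        rater_b = table[rater_cols].rename(
            columns={c: c[: -len(RATER_B_SUFFIX)] for c in rater_cols}
        )
        table = table.drop(columns=rater_cols)
    return Cohort(table, outcome, site=site, rater_b=rater_b)


# ---------------------------------------------------------------------------
# YAML config round-trip
# ---------------------------------------------------------------------------


def config_to_yaml(config: GeneratorConfig, path: str | Path | None = None) -> str:
    import yaml

    def spec_dict(p: PredictorSpec) -> dict:
        d = {"name": p.name, "kind": p.kind}
        for k, v in vars(p).items():
            if k in d or v is None or (k == "missing_rate" and v == 0.0):
                continue
            d[k] = v
        return d

    payload = {
        "n": config.n,
        "seed": config.seed,
        "site_label": config.site_label,
        "predictors": [spec_dict(p) for p in config.predictors],
        "true_rule": {
            "conditions": [
                [c.predictor, c.op, float(c.threshold)] for c in config.true_rule.conditions
            ],
            "leaf_risks": [float(r) for r in config.true_rule.leaf_risks],
            "default_risk": float(config.true_rule.default_risk),
        },
    }
    text = yaml.safe_dump(payload, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_from_yaml(source: str | Path) -> GeneratorConfig:
    """Load a GeneratorConfig from YAML text or a path to a YAML file."""
    import yaml

    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        text = Path(source).read_text()
    else:
        text = str(source)
    payload = yaml.safe_load(text)
    predictors = [PredictorSpec(**p) for p in payload["predictors"]]
    rule = TrueRuleConfig(
        conditions=[RuleCondition(p, op, thr) for p, op, thr in payload["true_rule"]["conditions"]],
        leaf_risks=payload["true_rule"]["leaf_risks"],
        default_risk=payload["true_rule"]["default_risk"],
    )
    config = GeneratorConfig(
        predictors, rule, n=payload["n"], seed=payload["seed"],
        site_label=payload.get("site_label", "cohort"),
    )
    config.validate()
    return config
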