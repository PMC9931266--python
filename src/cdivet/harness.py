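"""End-to-end study orchestration.

Runs the two-objective design: (1) internal vetting on a development
cohort — preprocessing, fitting a grid of interpretable CDIs, operating
point selection, the 90%-sensitivity elimination screen, variable- and
model-level stability, and a predictability ranking; then (2) frozen-model
external validation on a second cohort after explicit schema matching,
with a rank-concordance comparison between the internal prediction and the
external outcome.

Variable matching is explicit configuration, never fuzzy inference: every
variable a frozen model references must resolve to exactly one external
column or the run aborts naming the variable.  No information flows from
the external cohort into fitting or threshold selection — models and
thresholds are frozen before the external stage.
"""
from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics as dx
from . import preprocess as pp
from . import rule_models as rm
from . import stability as st
from . import synth_cohort as sc

__all__ = [
    "VariableMapEntry",
    "VariableMap",
    "MappingError",
    "match_variables",
    "apply_map",
    "external_validate",
    "PredictionTreeReport",
    "prediction_tree_report",
    "RankConcordance",
    "rank_agreement",
    "kendall_tau",
    "compare_marginals",
    "default_config",
    "run_pipeline",
]


class MappingError(KeyError):
    """A model-critical variable could not be matched between schemas."""


# ---------------------------------------------------------------------------
# Variable matching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariableMapEntry:
    source: str | None
    target: str | None
    kind: str  # direct | mapped | unmatched_source_only | unmatched_target_only
    transform: dict | None = None


@dataclass
class VariableMap:
    entries: list[VariableMapEntry]

    def resolved(self) -> dict[str, VariableMapEntry]:
        return {
            e.source: e for e in self.entries if e.kind in ("direct", "mapped")
        }

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "source": e.source,
                    "target": e.target,
                    "kind": e.kind,
                    "transform": e.transform,
                }
                for e in self.entries
            ],
            indent=2,
            sort_keys=True,
        )


def match_variables(
    source_schema,
    target_schema,
    map_spec: dict[str, str | dict] | None = None,
    critical: set[str] | frozenset[str] = frozenset(),
) -> VariableMap:
    """Validate an explicit source-to-target variable map.

    ``map_spec`` maps source names to a target name or to
    ``{"target": ..., "transform": {...}}``; source columns not named in
    the spec match a same-named target column directly when one exists.
    Unmatched model-critical variables raise :class:`MappingError`;
    other unmatched variables on either side are logged with disposition
    (the gender / femur-fracture / distracting-injury situation).
    """
    source = list(source_schema)
    target = list(target_schema)
    map_spec = dict(map_spec or {})
    entries: list[VariableMapEntry] = []
    used_targets: set[str] = set()
    for name in source:
        if name in map_spec:
            spec = map_spec[name]
            if spec is None:
                # adjudicated as having no counterpart at the target site
                if name in critical:
                    raise MappingError(f"model-critical variable {name!r} is unmatched")
                entries.append(VariableMapEntry(name, None, "unmatched_source_only"))
                continue
            if isinstance(spec, str):
                tgt, transform = spec, None
            else:
                tgt, transform = spec["target"], spec.get("transform")
            if tgt not in target:
                if name in critical:
                    raise MappingError(
                        f"model-critical variable {name!r} maps to unknown column {tgt!r}"
                    )
                entries.append(VariableMapEntry(name, None, "unmatched_source_only"))
                continue
            kind = "direct" if (tgt == name and transform is None) else "mapped"
            entries.append(VariableMapEntry(name, tgt, kind, transform))
            used_targets.add(tgt)
        elif name in target:
            entries.append(VariableMapEntry(name, name, "direct"))
            used_targets.add(name)
        else:
            if name in critical:
                raise MappingError(f"model-critical variable {name!r} is unmatched")
            entries.append(VariableMapEntry(name, None, "unmatched_source_only"))
    for name in target:
        if name not in used_targets:
            entries.append(VariableMapEntry(None, name, "unmatched_target_only"))
    resolved_targets = [e.target for e in entries if e.kind in ("direct", "mapped")]
    if len(set(resolved_targets)) != len(resolved_targets):
        raise MappingError("two source variables resolve to the same target column")
    return VariableMap(entries)


def _apply_transform(values: np.ndarray, transform: dict | None) -> np.ndarray:
    if transform is None:
        return values
    op = transform.get("op")
    if op == "linear":
        return values * transform.get("scale", 1.0) + transform.get("offset", 0.0)
    if op == "indicator_lt":
        # target stores the binary indicator [value < threshold]; synthesize a
        # source-scale column that reproduces any (source < threshold) condition
        t = transform["threshold"]
        return np.where(values == 1, t - 1, t).astype(float)
    raise ValueError(f"unknown transform {op!r}")


def apply_map(vmap: VariableMap, external_table: pd.DataFrame) -> pd.DataFrame:
    """External table re-expressed in the source (development) schema."""
    cols = {}
    for source, entry in vmap.resolved().items():
        cols[source] = _apply_transform(
            external_table[entry.target].to_numpy(dtype=float), entry.transform
        )
    return pd.DataFrame(cols, index=external_table.index)


# ---------------------------------------------------------------------------
# External validation (frozen models)
# ---------------------------------------------------------------------------


def external_validate(
    models: dict[str, rm.Model],
    thresholds: dict[str, float],
    external: sc.Cohort,
    vmap: VariableMap | None = None,
) -> dict[str, dx.DiagnosticReport]:
    """Evaluate frozen models at frozen thresholds on a mapped external cohort.

    No refitting and no threshold re-selection happen here by construction.
    """
    if external.n == 0:
        raise ValueError("empty external cohort")
    table = external.predictors if vmap is None else apply_map(vmap, external.predictors)
    y = external.outcome.to_numpy()
    reports = {}
    for name, model in models.items():
        risks = rm.predict_risk(model, table)
        reports[name] = dx.report_at_threshold(risks, y, thresholds[name])
    return reports


# ---------------------------------------------------------------------------
# Prediction tree report
# ---------------------------------------------------------------------------


@dataclass
class PredictionTreeReport:
    """First-match audit of a rule list on a cohort (tabular tree rendering)."""

    nodes: list[dict]  # condition, n, captured, risk
    residual_n: int
    residual_missed: int
    cumulative_captured: list[int]  # captured by the first k conditions, k=0..K
    monotone: bool

    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": self.nodes,
                "residual": {"n": self.residual_n, "outcomes_missed": self.residual_missed},
                "cumulative_captured": self.cumulative_captured,
                "monotone_node_risks": self.monotone,
            },
            indent=2,
            sort_keys=True,
        )


def prediction_tree_report(rule_list: rm.RuleList, cohort: sc.Cohort) -> PredictionTreeReport:
    """Per-condition first-match counts, outcomes captured, and node risks.

    Node counts partition the cohort; outcomes captured plus outcomes in
    the residual (very-low-risk) node equal the total positives.  Flags
    whether empirical node risks decrease monotonically down the list.
    """
    match = rule_list.first_match(cohort.predictors)
    y = cohort.outcome.to_numpy()
    nodes = []
    risks = []
    for i, cond in enumerate(rule_list.conditions):
        mask = match == i
        n = int(mask.sum())
        captured = int(y[mask].sum())
        risk = captured / n if n else float("nan")
        nodes.append(
            {"condition": str(cond), "n": n, "outcomes_captured": captured, "risk": risk}
        )
        risks.append(risk)
    residual = match == len(rule_list.conditions)
    cumulative = list(np.cumsum([0] + [node["outcomes_captured"] for node in nodes]).astype(int))
    observed = [r for r in risks if not np.isnan(r)]
    monotone = all(b <= a for a, b in zip(observed, observed[1:]))
    return PredictionTreeReport(
        nodes=nodes,
        residual_n=int(residual.sum()),
        residual_missed=int(y[residual].sum()),
        cumulative_captured=[int(c) for c in cumulative],
        monotone=monotone,
    )


# ---------------------------------------------------------------------------
# Rank concordance
# ---------------------------------------------------------------------------


def kendall_tau(internal: list[str], external: list[str]) -> float:
    """Kendall tau by direct pairwise concordance count."""
    pos = {m: i for i, m in enumerate(external)}
    n = len(internal)
    concordant = discordant = 0
    for i in range(n):
        for j in range(i + 1, n):
            if pos[internal[i]] < pos[internal[j]]:
                concordant += 1
            else:
                discordant += 1
    pairs = n * (n - 1) // 2
    return (concordant - discordant) / pairs if pairs else 1.0


@dataclass
class RankConcordance:
    internal_rank: list[str]
    external_rank: list[str]
    kendall_tau: float
    exact_match: bool

    def to_json(self) -> str:
        return json.dumps(
            {
                "internal_rank": self.internal_rank,
                "external_rank": self.external_rank,
                "kendall_tau": self.kendall_tau,
                "exact_match": self.exact_match,
            },
            indent=2,
            sort_keys=True,
        )


def rank_agreement(internal: list[str], external: list[str]) -> RankConcordance:
    if set(internal) != set(external) or len(internal) != len(external):
        raise ValueError("rankings cover different model sets")
    return RankConcordance(
        internal_rank=list(internal),
        external_rank=list(external),
        kendall_tau=kendall_tau(internal, external),
        exact_match=list(internal) == list(external),
    )


# ---------------------------------------------------------------------------
# Marginal comparison (tabular stand-in for distribution plots)
# ---------------------------------------------------------------------------


def compare_marginals(cohort_a: sc.Cohort, cohort_b: sc.Cohort) -> pd.DataFrame:
    """Per-variable prevalence/mean in both cohorts with absolute difference."""
    rows = []
    shared = [c for c in cohort_a.predictors.columns if c in cohort_b.predictors.columns]
    for col in shared:
        a = cohort_a.predictors[col].dropna()
        b = cohort_b.predictors[col].dropna()
        binary = np.isin(pd.concat([a, b]).unique(), (0.0, 1.0)).all()
        rows.append(
            {
                "variable": col,
                "kind": "binary" if binary else "ordinal",
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "abs_difference": float(abs(a.mean() - b.mean())),
            }
        )
    rows.append(
        {
            "variable": "outcome",
            "kind": "binary",
            "mean_a": cohort_a.prevalence,
            "mean_b": cohort_b.prevalence,
            "abs_difference": abs(cohort_a.prevalence - cohort_b.prevalence),
        }
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def default_config(seed: int = 0) -> dict:
    """Default study configuration (synthetic cohorts at the study sizes)."""
    return {
        "seed": seed,
        "n_internal": 12_044,
        "n_external": 2_188,
        "dev_frac": 0.663,
        "w": 5.0,
        "screen_sens_floor": 0.90,
        "operating_sens_floor": 0.95,
        "class_weight": 5.0,
        "max_missing": 0.05,
        "min_kappa_ci_low": 0.4,
        "phi_threshold": 0.95,
        "n_perm": 100,
        "refit_seeds": 3,
        "models": ["pecarn_rule_list", "cart_tree", "cart_rule_list", "rule_ensemble", "logistic"],
        "cart_tree": {"max_depth": 4, "min_leaf": 20},
        "cart_rule_list": {"max_rules": 7, "min_leaf": 20},
        "rule_ensemble": {"n_trees": 30, "tree_depth": 2, "max_rules": 8, "min_leaf": 20},
        # sex is recorded at the development site only (no external
        # counterpart), so it is adjudicated unmatched up front and kept
        # out of model fitting entirely
        "map_spec": {"sex_male": None},
        "write_cohorts": False,
    }


def _fitters(cfg: dict, dev: sc.Cohort) -> dict[str, callable]:
    cw = cfg["class_weight"]
    tree_p = cfg.get("cart_tree", {})
    list_p = cfg.get("cart_rule_list", {})
    ens_p = cfg.get("rule_ensemble", {})
    return {
        "pecarn_rule_list": lambda seed: rm.pecarn_reference_cdi(),
        "cart_tree": lambda seed: rm.fit_cart_tree(
            dev, class_weight=cw, **tree_p
        ),
        "cart_rule_list": lambda seed: rm.fit_cart_rule_list(
            dev, class_weight=cw, **list_p
        ),
        "rule_ensemble": lambda seed: rm.fit_rule_ensemble(
            dev, class_weight=cw, seed=seed, **ens_p
        ),
        "logistic": lambda seed: rm.fit_logistic(dev),
    }


class _Json(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def _dump(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, cls=_Json) + "\n")


def run_pipeline(config: dict | None = None, out_dir: str | Path | None = None) -> dict:
    """Execute the full study and (optionally) write the artifact bundle.

    Stage order: generate -> preprocess -> split -> fit grid -> internal
    reports and curves -> elimination screen -> stability -> predictability
    ranking -> schema matching -> frozen external validation -> rank
    concordance -> marginal comparison -> bundle.  Wall time per stage is
    logged to a separate timings file (reported, never asserted).
    """
    cfg = default_config()
    cfg.update(config or {})
    seed = int(cfg["seed"])
    timings: dict[str, float] = {}
    bundle: dict = {"config": {k: v for k, v in cfg.items()}}

    def stage(name: str):
        return _Stage(name, timings)

    with stage("generate"):
        internal_cfg = sc.pecarn_like_config(n=cfg["n_internal"], seed=seed)
        external_cfg = sc.pedsrc_like_config(internal_cfg, n=cfg["n_external"], seed=seed + 1)
        internal = sc.generate_cohort(internal_cfg)
        external = sc.generate_cohort(external_cfg)

    with stage("preprocess"):
        clean, screen = pp.preprocess_cohort(
            internal,
            max_missing=cfg["max_missing"],
            min_kappa_ci_low=cfg["min_kappa_ci_low"],
            phi_threshold=cfg["phi_threshold"],
        )
        excluded = [s for s, v in (cfg["map_spec"] or {}).items() if v is None]
        clean.predictors = clean.predictors.drop(
            columns=[c for c in excluded if c in clean.predictors.columns]
        )
        split = pp.stratified_split(clean, dev_frac=cfg["dev_frac"], seed=seed + 2)
        dev, val = split.development, split.validation

    with stage("fit"):
        fitters = _fitters(cfg, dev)
        models = {name: fitters[name](seed + 3) for name in cfg["models"]}

    with stage("internal_reports"):
        w = cfg["w"]
        dev_y = dev.outcome.to_numpy()
        val_y = val.outcome.to_numpy()
        thresholds, dev_reports, val_reports, curves = {}, {}, {}, {}
        for name, model in models.items():
            risks_dev = rm.predict_risk(model, dev)
            curve = dx.sens_spec_curve(risks_dev, dev_y)
            op = dx.select_operating_point(curve, w=w, sens_floor=cfg["operating_sens_floor"])
            thresholds[name] = op.threshold
            dev_reports[name] = dx.report_at_threshold(risks_dev, dev_y, op.threshold)
            val_reports[name] = dx.report_at_threshold(
                rm.predict_risk(model, val), val_y, op.threshold
            )
            curves[name] = curve

    with stage("screen"):
        surviving = dx.screen_cdis(dev_reports, min_sens=cfg["screen_sens_floor"])
        screened_models = {n: models[n] for n in surviving}

    with stage("stability"):
        stab_table = st.build_stability_table(
            screened_models,
            val,
            thresholds,
            w=w,
            n_perm=cfg["n_perm"],
            seed=seed + 4,
        )
        var_rank = st.variable_stability_rank(stab_table)
        refit = {}
        for name in surviving:
            spread = rm.refit_randomness(fitters[name], dev, n_seeds=max(cfg["refit_seeds"], 2), w=w)
            refit[name] = spread
        model_stab = {
            name: st.performance_drop(
                dev_reports[name], val_reports[name], w=w, refit=refit[name]
            )
            for name in surviving
        }

    with stage("rank"):
        ranking = st.rank_cdis(
            {n: dev_reports[n] for n in surviving},
            {n: val_reports[n] for n in surviving},
            model_stab,
        )
        internal_rank = [r["model"] for r in ranking]

    with stage("external"):
        # carry the frozen development-time preprocessing onto the external
        # cohort (same drops, same imputation rule, same merged columns)
        ext_processed = pp.apply_screen(external, screen)
        critical = set()
        for model in screened_models.values():
            critical |= set(rm.model_variables(model))
        vmap = match_variables(
            dev.predictors.columns, ext_processed.predictors.columns,
            cfg["map_spec"], critical,
        )
        ext_reports = external_validate(
            screened_models, thresholds, ext_processed, vmap
        )
        ext_rank_rows = sorted(
            (
                (name, dx.weighted_score(rep.sensitivity, rep.specificity, w))
                for name, rep in ext_reports.items()
            ),
            key=lambda t: (-t[1], t[0]),
        )
        external_rank = [name for name, _ in ext_rank_rows]
        concordance = rank_agreement(internal_rank, external_rank)

    with stage("reports"):
        marginals = compare_marginals(internal, external)
        reference = models.get("pecarn_rule_list")
        tree_reports = {}
        if isinstance(reference, rm.RuleList):
            tree_reports["validation"] = prediction_tree_report(reference, val)
            tree_reports["external"] = prediction_tree_report(
                reference,
                sc.Cohort(
                    apply_map(vmap, ext_processed.predictors),
                    external.outcome,
                    external.site,
                ),
            )

    bundle.update(
        {
            "screen_report": json.loads(screen.to_json()),
            "split": {"n_dev": dev.n, "n_val": val.n, "dev_prevalence": dev.prevalence,
                      "val_prevalence": val.prevalence},
            "thresholds": thresholds,
            "dev_reports": {n: r.to_dict() for n, r in dev_reports.items()},
            "val_reports": {n: r.to_dict() for n, r in val_reports.items()},
            "surviving": surviving,
            "stability_table": json.loads(stab_table.to_frame().to_json(orient="index")),
            "variable_rank": var_rank,
            "model_stability": {
                n: {"dev_score": s.dev_score, "val_score": s.val_score,
                    "drop": s.drop, "refit_spread": s.refit_spread}
                for n, s in model_stab.items()
            },
            "ranking": ranking,
            "variable_map": json.loads(vmap.to_json()),
            "external_reports": {n: r.to_dict() for n, r in ext_reports.items()},
            "rank_concordance": json.loads(concordance.to_json()),
            "marginals": marginals.to_dict(orient="records"),
            "prediction_tree": {k: json.loads(v.to_json()) for k, v in tree_reports.items()},
        }
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "models").mkdir(exist_ok=True)
        for name, model in models.items():
            (out / "models" / f"{name}.json").write_text(rm.model_to_json(model))
        _dump(out / "screen_report.json", bundle["screen_report"])
        _dump(out / "thresholds.json", bundle["thresholds"])
        _dump(out / "reports_internal.json",
              {"development": bundle["dev_reports"], "validation": bundle["val_reports"]})
        _dump(out / "reports_external.json", bundle["external_reports"])
        _dump(out / "ranking.json", bundle["ranking"])
        _dump(out / "rank_concordance.json", bundle["rank_concordance"])
        _dump(out / "variable_map.json", bundle["variable_map"])
        _dump(out / "variable_rank.json", bundle["variable_rank"])
        _dump(out / "prediction_tree.json", bundle["prediction_tree"])
        stab_table.to_frame().to_csv(out / "stability_table.csv")
        marginals.to_csv(out / "marginals.csv", index=False)
        for name, curve in curves.items():
            curve.to_frame().to_csv(out / f"curve_{name}.csv", index=False)
        (out / "summary.md").write_text(_render_summary(bundle))
        if cfg.get("write_cohorts"):
            sc.write_cohort_csv(internal, out / "cohort_internal.csv")
            sc.write_cohort_csv(external, out / "cohort_external.csv")
        # hardware-dependent; deliberately outside the determinism guarantee
        _dump(out / "timings.json", timings)

    bundle["timings"] = timings
    return bundle


class _Stage:
    def __init__(self, name: str, sink: dict):
        self.name = name
        self.sink = sink

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.sink[self.name] = time.perf_counter() - self.t0
        if exc is not None:
            raise RuntimeError(f"pipeline stage {self.name!r} failed") from exc


def _render_summary(bundle: dict) -> str:
    lines = ["# Study summary", ""]
    lines.append("## Internal ranking (validation weighted score, drop, refit spread)")
    for row in bundle["ranking"]:
        lines.append(
            f"{row['rank']}. {row['model']}: val={row['val_score']:.4f} "
            f"dev={row['dev_score']:.4f} drop={row['drop']:.4f} "
            f"refit_spread={row['refit_spread']:.2e}"
        )
    lines.append("")
    lines.append("## External validation")
    for name, rep in bundle["external_reports"].items():
        lines.append(
            f"- {name}: sensitivity {dx.format_percent(rep['sensitivity'])}, "
            f"specificity {dx.format_percent(rep['specificity'])}, "
            f"Brier {dx.format_brier(rep['brier'])}"
        )
    lines.append("")
    rc = bundle["rank_concordance"]
    lines.append(
        f"Rank concordance (internal vs external): tau = {rc['kendall_tau']:.3f}, "
        f"exact match = {rc['exact_match']}"
    )
    lines.append("")
    lines.append("## Most stable predictor variables")
    for v in bundle["variable_rank"][:5]:
        lines.append(f"- {v}")
    lines.append("")
    return "\n".join(lines)
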