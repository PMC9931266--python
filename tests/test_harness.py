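"""Schema matching, frozen external validation, reports, end-to-end pipeline."""
import copy
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import cdivet.diagnostics as dx
import cdivet.harness as hn
import cdivet.rule_models as rm
import cdivet.synth_cohort as sc

from conftest import random_binary_cohort


class TestMatchVariables:
    def test_identity_schemas_all_direct(self):
        vmap = hn.match_variables(["a", "b"], ["a", "b"])
        assert all(e.kind == "direct" for e in vmap.entries)

    def test_missing_critical_variable_is_hard_error(self):
        with pytest.raises(hn.MappingError, match="gcs"):
            hn.match_variables(["gcs", "x"], ["x"], critical={"gcs"})

    def test_unmatched_noncritical_logged(self):
        vmap = hn.match_variables(["sex_male", "x"], ["x", "femur"], {"sex_male": None})
        kinds = {e.source or e.target: e.kind for e in vmap.entries}
        assert kinds["sex_male"] == "unmatched_source_only"
        assert kinds["femur"] == "unmatched_target_only"

    def test_renamed_column_with_threshold_transform_round_trips(self, rng):
        """A renamed GCS column stored as a below-threshold indicator yields
        identical predictions on identical-content cohorts."""
        n = 200
        source = pd.DataFrame(
            {
                "gcs": rng.choice([3.0, 12.0, 14.0, 15.0], size=n),
                "abd_tenderness": rng.integers(0, 2, n).astype(float),
            }
        )
        target = pd.DataFrame(
            {
                "gcs_under_14": (source["gcs"] < 14).astype(float),
                "tender": source["abd_tenderness"],
            }
        )
        vmap = hn.match_variables(
            source.columns,
            target.columns,
            {
                "gcs": {
                    "target": "gcs_under_14",
                    "transform": {"op": "indicator_lt", "threshold": 14},
                },
                "abd_tenderness": "tender",
            },
        )
        model = rm.RuleList(
            [rm.RuleCondition("gcs", "<", 14), rm.RuleCondition("abd_tenderness", "==", 1)],
            [0.5, 0.2],
            0.01,
        )
        mapped = hn.apply_map(vmap, target)
        np.testing.assert_array_equal(
            rm.predict_risk(model, mapped), rm.predict_risk(model, source)
        )

    def test_duplicate_target_rejected(self):
        with pytest.raises(hn.MappingError, match="same target"):
            hn.match_variables(["a", "b"], ["x"], {"a": "x", "b": "x"})


class TestExternalValidate:
    def test_identical_cohort_reproduces_reports(self, rng):
        cohort = random_binary_cohort(rng, n=300, p=4, signal={"x0": 2.0})
        model = rm.fit_cart_rule_list(cohort, min_leaf=10)
        risks = rm.predict_risk(model, cohort)
        t = dx.select_operating_point(
            dx.sens_spec_curve(risks, cohort.outcome.to_numpy())
        ).threshold
        internal = dx.report_at_threshold(risks, cohort.outcome.to_numpy(), t)
        external = hn.external_validate({"m": model}, {"m": t}, cohort)["m"]
        assert external.to_dict() == internal.to_dict()

    def test_truncated_reference_matches_full_when_weak_signal_absent(self):
        cfg = sc.pedsrc_like_config(n=2188)
        silent = sc.shift_site(
            cfg, prevalence={name: 0.0 for name in sc.weak_predictors()}
        )
        cohort = sc.generate_cohort(silent)
        cohort.predictors = cohort.predictors.fillna(0.0)
        full = rm.pecarn_reference_cdi()
        trunc = rm.truncate_rule_list(full, 3)
        thresholds = {"full": min(full.leaf_risks), "trunc": min(trunc.leaf_risks)}
        reports = hn.external_validate(
            {"full": full, "trunc": trunc}, thresholds, cohort
        )
        assert reports["full"].sensitivity == reports["trunc"].sensitivity

    def test_no_information_flow_from_external_to_models(self, rng):
        dev = random_binary_cohort(rng, n=200, p=4, signal={"x0": 2.0})
        before = rm.model_to_json(rm.fit_cart_rule_list(dev, min_leaf=10))
        external = random_binary_cohort(rng, n=100, p=4)
        external.predictors.iloc[:, :] = 1.0  # mutate external data wildly
        after = rm.model_to_json(rm.fit_cart_rule_list(dev, min_leaf=10))
        assert before == after

    def test_empty_external_rejected(self):
        with pytest.raises(ValueError):
            hn.external_validate(
                {},
                {},
                sc.Cohort(pd.DataFrame({"x": []}), pd.Series([], dtype=int)),
            )


class TestPredictionTreeReport:
    def test_all_negative_cohort_in_residual(self):
        cdi = rm.pecarn_reference_cdi()
        cols = {name: np.zeros(50) for name, _, _ in rm.DEFAULT_REFERENCE_CONDITIONS}
        cols["gcs"] = np.full(50, 15.0)
        cohort = sc.Cohort(pd.DataFrame(cols), pd.Series(np.zeros(50, dtype=int)))
        report = hn.prediction_tree_report(cdi, cohort)
        assert report.residual_n == 50
        assert all(node["n"] == 0 for node in report.nodes)

    def test_conservation_on_random_cohorts(self, rng):
        for _ in range(10):
            cohort = random_binary_cohort(rng, n=100, p=3)
            rl = rm.RuleList(
                [rm.RuleCondition("x0", "==", 1), rm.RuleCondition("x1", "==", 1)],
                [0.5, 0.3],
                0.1,
            )
            report = hn.prediction_tree_report(rl, cohort)
            assert sum(n["n"] for n in report.nodes) + report.residual_n == cohort.n
            captured = sum(n["outcomes_captured"] for n in report.nodes)
            assert captured + report.residual_missed == cohort.outcome.sum()
            assert report.cumulative_captured[-1] == captured

    def test_capture_curve_flat_after_three_when_weak_conditions_silent(self):
        cfg = sc.pedsrc_like_config(n=2188)
        silent = sc.shift_site(
            cfg, prevalence={name: 0.0 for name in sc.weak_predictors()}
        )
        cohort = sc.generate_cohort(silent)
        cohort.predictors = cohort.predictors.fillna(0.0)
        report = hn.prediction_tree_report(rm.pecarn_reference_cdi(), cohort)
        cc = report.cumulative_captured
        assert cc[3:] == [cc[3]] * (len(cc) - 3)


class TestRankAgreement:
    def test_identical_orderings(self):
        models = ["a", "b", "c", "d", "e"]
        rc = hn.rank_agreement(models, list(models))
        assert rc.kendall_tau == 1.0 and rc.exact_match

    def test_full_reversal(self):
        rc = hn.rank_agreement(["a", "b", "c", "d"], ["d", "c", "b", "a"])
        assert rc.kendall_tau == -1.0 and not rc.exact_match

    def test_matches_scipy_pairwise_count(self, rng):
        models = [f"m{i}" for i in range(6)]
        for _ in range(10):
            ext = list(rng.permutation(models))
            tau = hn.kendall_tau(models, ext)
            ranks_int = [models.index(m) for m in models]
            ranks_ext = [ext.index(m) for m in models]
            expected = scipy.stats.kendalltau(ranks_int, ranks_ext).statistic
            assert tau == pytest.approx(expected)

    def test_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hn.rank_agreement(["a", "b"], ["a", "c"])


class TestCompareMarginals:
    def test_identical_cohorts_zero_differences(self, rng):
        cohort = random_binary_cohort(rng, n=100, p=3)
        frame = hn.compare_marginals(cohort, cohort)
        assert (frame["abs_difference"] == 0).all()

    def test_default_site_shift_visible(self):
        internal = sc.generate_cohort(sc.pecarn_like_config(n=12_044, seed=0))
        external = sc.generate_cohort(sc.pedsrc_like_config(n=2_188))
        frame = hn.compare_marginals(internal, external).set_index("variable")
        assert frame.loc["mvc", "abs_difference"] == pytest.approx(0.145, abs=0.03)
        assert frame.loc["outcome", "abs_difference"] == pytest.approx(0.011, abs=0.008)


class TestRunPipeline:
    CFG = {"n_internal": 3000, "n_external": 900, "n_perm": 10, "seed": 0,
           "refit_seeds": 2}

    def test_smoke_and_artifacts(self, tmp_path):
        bundle = hn.run_pipeline(dict(self.CFG), out_dir=tmp_path / "b")
        for artifact in (
            "ranking.json", "rank_concordance.json", "reports_internal.json",
            "reports_external.json", "stability_table.csv", "summary.md",
            "models/pecarn_rule_list.json", "timings.json",
        ):
            assert (tmp_path / "b" / artifact).exists(), artifact
        assert bundle["surviving"]  # at least one CDI passes the screen
        assert set(bundle["rank_concordance"]["internal_rank"]) == set(bundle["surviving"])

    def test_byte_identical_artifacts_under_fixed_seed(self, tmp_path):
        hn.run_pipeline(dict(self.CFG), out_dir=tmp_path / "r1")
        hn.run_pipeline(dict(self.CFG), out_dir=tmp_path / "r2")
        files1 = sorted(
            p.relative_to(tmp_path / "r1")
            for p in (tmp_path / "r1").rglob("*")
            if p.is_file()
        )
        files2 = sorted(
            p.relative_to(tmp_path / "r2")
            for p in (tmp_path / "r2").rglob("*")
            if p.is_file()
        )
        assert files1 == files2
        for rel in files1:
            if rel.name == "timings.json":  # hardware-dependent by design
                continue
            assert (tmp_path / "r1" / rel).read_bytes() == (
                tmp_path / "r2" / rel
            ).read_bytes(), rel

    def test_different_seed_changes_cohort_dependent_artifacts(self, tmp_path):
        b1 = hn.run_pipeline(dict(self.CFG), out_dir=None)
        b2 = hn.run_pipeline(dict(self.CFG, seed=1), out_dir=None)
        assert b1["split"] != b2["split"]

    def test_constructed_concordance_scenario(self):
        """With an overfit-prone deep tree and a stable short rule list in the
        grid, the internal predictability ranking carries to external data."""
        cfg = dict(
            self.CFG,
            models=["pecarn_rule_list", "cart_rule_list", "cart_tree"],
            cart_tree={"max_depth": 8, "min_leaf": 1},
            cart_rule_list={"max_rules": 3, "min_leaf": 50},
            n_internal=6000,
            n_external=2000,
        )
        bundle = hn.run_pipeline(cfg, out_dir=None)
        rc = bundle["rank_concordance"]
        assert rc["kendall_tau"] == 1.0
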