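# cdivet

Predictability–computability–stability (PCS) vetting for rule-based
clinical decision instruments (CDIs).

## The problem

A CDI is an explicit rule applied to patient findings — e.g. "if none of
these seven findings is present, the child is at very low risk of
intra-abdominal injury undergoing acute intervention (IAI-I) and CT can be
avoided". Before a CDI is trusted on new populations it needs external
validation, which is slow and expensive. PCS vetting is a computational
step in between: derive several *interpretable* candidate CDIs, screen
them by predictive performance, measure how stable their constituent
predictor variables and their performance are, and only then invest in
external validation. `cdivet` implements that pipeline end-to-end for
tabular patient cohorts (binary/ordinal findings, a rare binary outcome),
together with a synthetic trauma-cohort generator that stands in for the
original development (N=12,044, outcome prevalence 1.7%) and external
(N=2,188, prevalence 2.8%) datasets, which are not publicly deposited.

At its core:

- **Rule lists** `IF c₁: risk r₁ ELIF c₂: risk r₂ … ELSE r₀` with
  r₁ > r₂ > … > r₀; a patient is *very low risk* iff no condition fires.
- **CART induction from scratch**: binary recursive partitioning and
  one-sided rule-list peeling by the Gini criterion
  g = 1 − p² − (1 − p)², with an outcome-class weight for the rare
  outcome and fully deterministic tie-breaking.
- **The 5:1 weighted score** S = (5·sens + spec)/6 for ranking
  sensitivity-critical screening rules, with a 90% development-sensitivity
  elimination screen and a 95% floor for operating-threshold selection.
- **Stability**: per-variable frequency and permutation importance across
  CDIs; per-model development→validation performance drop and
  refit-randomness spread.
- **Frozen external validation**: explicit variable mapping between
  schemas, frozen preprocessing/models/thresholds, and Kendall-tau
  concordance between the internal (PCS) ranking and the external one.

See `docs/methods.md` for the full model and parameter account.

## Worked example

```python
import cdivet as cv

bundle = cv.run_pipeline({"seed": 1})          # full synthetic study
for row in bundle["ranking"]:
    print(row["rank"], row["model"],
          f"val={row['val_score']:.4f}", f"drop={row['drop']:.4f}")
print("external rank concordance tau =",
      bundle["rank_concordance"]["kendall_tau"])
print("top stability variables:", bundle["variable_rank"][:3])
```

prints

```
1 cart_tree val=0.8801 drop=0.0021
2 cart_rule_list val=0.8755 drop=0.0153
3 pecarn_rule_list val=0.8755 drop=0.0153
4 logistic val=0.8596 drop=0.0164
5 rule_ensemble val=0.8333 drop=0.0000
external rank concordance tau = 0.4
top stability variables: ['abd_trauma_or_seatbelt_sign', 'gcs', 'abd_tenderness']
```

Reading this: each CDI was fitted on the development split (66.3% of the
12,044-patient internal cohort), its operating threshold chosen on the
development sensitivity–specificity curve under the 95% sensitivity floor,
and evaluated frozen on the validation split; `val` is the 5:1 weighted
score there and `drop` the development→validation decline (larger drop =
less stable). The depth-4 CART tree wins internally, but on the shifted
2,188-patient external cohort its sensitivity falls below the fitted and
reference rule lists, which overtake it — the ranking agreement is only
partial (tau = 0.4), exactly the kind of shift-fragility the vetting stage
is meant to surface. The three embedded strong findings are recovered as
the most stable variables.

The same study is available from the shell:

```bash
cdivet run --seed 1 --out bundle/        # artifacts: JSON, CSV, markdown
cdivet report --bundle bundle/
# or stepwise:
cdivet generate --out data/ --seed 1
cdivet vet --dev data/cohort_internal.csv --out vetted/
cdivet validate --models vetted/models --external data/cohort_external.csv --out external/
```

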