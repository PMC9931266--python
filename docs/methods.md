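# Methods

`cdivet` implements a predictability–computability–stability (PCS) vetting
pipeline for rule-based clinical decision instruments (CDIs), built around
the pediatric blunt-torso-trauma use case: identifying children at very low
risk of intra-abdominal injury undergoing acute intervention (IAI-I), so
that CT imaging can be avoided safely. This note records the models,
parameters, numerical choices and limitations; every number quoted here is
computed by the test suite or by `scripts/acceptance.py`, not asserted from
elsewhere.

## The models

All candidate CDIs are explicit rule structures over named clinical
findings, capped at ten logical steps so a clinician can execute them in
real time:

- **Rule list** — ordered `(condition, risk)` pairs with a default leaf. A
  patient takes the risk of the first condition that fires; a patient is
  "very low risk" iff no condition fires. The frozen seven-variable
  reference rule (abdominal wall trauma/seat-belt sign; GCS < 14; abdominal
  tenderness; thoracic wall trauma; abdominal pain complaint; decreased
  breath sounds; vomiting) is a rule list with `provenance="reference"` and
  strictly decreasing leaf risks.
- **CART decision tree** — greedy binary recursive partitioning maximizing
  the size-weighted Gini impurity decrease, `1 − p² − (1−p)²` per node.
- **CART rule list** — iterative one-sided partitioning: at each step the
  best Gini split of the remaining patients is found and the *higher-risk*
  side is peeled off as a leaf; the remainder becomes the default leaf.
  Peeling the high-risk side reproduces the derivation style in which
  high-risk subgroups are identified sequentially and node risks decrease
  down the list.
- **Rule ensemble** — conjunctive rules mined from root-to-node paths of
  bagged shallow CART trees, deduplicated, then selected greedily while
  they improve the 5:1 weighted score of the OR-of-rules classifier; an
  L2-penalized logistic link maps rule activations to risks. Candidate
  rules whose firing subgroup carries at-or-below base-rate risk (e.g.
  mined complement paths such as `finding == 0`) are inadmissible: without
  this, greedy selection under a sensitivity-weighted score degenerates to
  the everyone-positive rule at rare-outcome prevalences.
- **Logistic baseline** — a linear score under the same risk contract.

Published third-party rule learners (Bayesian rule lists, iterative random
forests, optimal sparse trees, greedy tree sums) are *not* re-implemented;
any object exposing `predict(cohort) -> risks in [0,1]` and a `variables`
attribute plugs into the same screening, stability and validation stages.

### Class imbalance

The outcome is rare (~1.7%). Impurity and leaf risks use an outcome-class
weight (default 5, mirroring the 5:1 sensitivity preference below): a node
with `pos`/`neg` raw counts contributes weighted counts `(5·pos, neg)`.
Weighted leaf risks are a strictly monotone transform of the raw empirical
fraction, so sensitivity–specificity curves and operating-point selection
are unaffected; Brier scores are computed on the weighted risks and are
therefore a measure of the deployed score's calibration, not of the raw
event-rate calibration.

### Determinism

Tie-breaks everywhere are column order, then ascending threshold. CART
tree and rule-list fitting use no randomness at all, so the refit-spread
stability marker is exactly zero for them; the rule ensemble and the
synthetic generator take explicit seeds, with per-column/per-purpose
substreams derived from a single master seed via SHA-256 so results do not
depend on column order.

## Diagnostics and screening

For a classification at risk threshold `t` (positive iff `risk ≥ t`) the
full battery is reported: sensitivity, specificity, NPV, PPV, LR±, F1,
accuracy, and the Brier score `mean((risk − outcome)²)`. Ratios with zero
denominators are reported as infinity/NaN with explicit flags, never
clamped. Threshold-free comparison uses sensitivity–specificity curves
with one point per distinct predicted risk plus an all-negative sentinel
at `+inf`.

CDIs are compared by the weighted score `(5·sens + spec)/6`. Two
sensitivity floors coexist deliberately: a 90% *elimination screen* on the
development set (CDIs below it are dropped before stability analysis) and
a 95% floor used when *selecting the operating threshold* on the
development curve (if no point meets it, the maximum-sensitivity point is
returned flagged). Thresholds are frozen along with the models before any
external data is touched.

## Stability

- **Variable level** — per-variable frequency (how many screened CDIs
  structurally reference it) and permutation importance: the mean drop in
  the 5:1 weighted score over `n_perm` within-cohort shuffles of that
  column (default 100; the replicate experiments use 20 for speed).
  Variables a model never references short-circuit to exactly 0. Variables
  are ranked by frequency (descending), then mean non-zero importance,
  then name — the combination rule is this package's documented choice;
  no canonical one exists.
- **Model level** — the development→validation drop in weighted score and
  the refit-randomness spread. CDIs are ranked by validation score
  (descending), then drop (ascending), then refit spread (ascending).

## External validation

Variable matching between the development and external schemas is explicit
configuration, never fuzzy inference: a map entry renames a column,
optionally with a transform (`linear`, or `indicator_lt` for a site that
stored an ordinal finding as a below-threshold flag), or declares a
variable unmatched (`null`). Variables adjudicated unmatched up front
(e.g. `sex_male`, recorded at the development site only) are excluded from
model fitting entirely, mirroring expert pre-adjudication. A
model-critical variable that cannot be resolved aborts the run naming the
variable. The development-time screening decisions (drops, imputation
rule, merged columns) are applied to the external cohort *frozen* — nothing
is re-derived from external data, and models/thresholds are immutable at
this stage.

Rank concordance between the internal (PCS) ranking and the external
ranking is summarized by Kendall's tau via direct pairwise concordance
counting, plus an exact-match flag. The prediction-tree report gives
per-condition first-match counts, outcomes captured, node risks, a
monotonicity flag and the cumulative-capture curve; counts always
partition the cohort.

## Preprocessing rules

Order is fixed: missingness filter → reliability filter → median
imputation → redundancy merge → stratified split.

- Missingness: drop iff the missing fraction is *strictly* greater than 5%
  (a column at exactly 5% is kept — literal reading of "more than 5%").
- Reliability: Cohen's kappa between duplicate ratings with the
  Fleiss–Cohen–Everitt asymptotic 95% CI (via
  `statsmodels.stats.inter_rater.cohens_kappa`); drop iff the CI lower
  bound is below 0.4. Variables without duplicate ratings pass unscreened
  but are logged. Kappa is undefined (NaN, flagged) when both raters use a
  single category.
- Imputation: column median of observed values; for binary columns the
  majority value, exact ties to 0.
- Redundancy: binary pairs with |phi| ≥ 0.95 (configurable; no canonical
  threshold exists) are merged by logical OR into `<a>_or_<b>`, with
  transitive closure of qualifying pairs. OR is used because the
  predictors are presence flags and OR preserves sensitivity.
- Split: outcome-stratified, `round(frac · n_class)` per class; the
  default fraction 0.663 reproduces a 7,985 / 4,059 division of 12,044
  patients. (A conflicting 80:20 figure appears alongside the 66/34 counts
  in the source material; the counts win.)

## The synthetic cohort generator

The original development (N=12,044, IAI-I prevalence 1.7%) and external
(N=2,188, prevalence 2.8%) cohorts are not publicly deposited, so the
generator emulates their statistical skeleton. What it reproduces:

- marginal prevalences where published (MVC 31.8% internal / 46.3%
  external; age < 2 years 9.7%; outcome 1.7% / 2.8%);
- an ordinal GCS on 3..15 with 80% mass at 15 and P(GCS < 14) = 0.08;
  binarization at 14 happens in the models, not the generator;
- an outcome drawn per patient as Bernoulli of the first matching
  condition of an embedded seven-condition true rule with strictly
  decreasing leaf risks (0.080, 0.045, 0.022, 0.005, 0.0035, 0.002,
  0.0007; default 0.00008). The three "strong" conditions carry large risk
  steps and the four "weak" ones small increments, so stability analysis
  has a recoverable ground truth; the analytic implied prevalence is
  1.70%. The weak-vs-strong risk separation and the weak-strata
  prevalences were calibrated once so that (a) the strong conditions are
  identifiable from n=8,000 cohorts and (b) adjacent stratum risks are
  separated by ≥ ~2.3 standard errors at n=200,000, making the
  monotonicity check statistically meaningful rather than a coin flip;
- MCAR missingness per column, injected after outcome assignment
  (including one column at 8% to exercise the 5% screen);
- a redundant pair at phi 0.98 (femur fracture / thigh deformity), child
  generated from the parent by the closed form
  `P(child=1, parent=1) = phi·sqrt(p(1−p)q(1−q)) + pq`;
- duplicate-rater columns at target Cohen's kappa: the second rating
  equals the first with probability kappa, otherwise it is an independent
  redraw at the realized prevalence, giving `p_o = κ + (1−κ)p_e` and hence
  an expected kappa exactly at target, with symmetric disagreements
  (including one column at kappa 0.25 to exercise the reliability screen);
- the external site as a derived config: MVC prevalence overridden to
  46.3%, leaf risks scaled uniformly so the implied prevalence is 2.8%
  (prevalence is linear in the scale, so the solve is exact), and no
  `sex_male` column (a one-sided schema mismatch).

What it does **not** emulate: correlations among the seven rule predictors
(unpublished — they are independent here), informative missingness,
injury-severity structure, vitals, or longitudinal records. Passing tests
therefore demonstrate that the *pipeline machinery* behaves as specified
under a known ground truth, not that any particular clinical conclusion
transfers to real trauma registries.

## Problem sizes used by the checks

The acceptance script runs the full study at the study sizes
(12,044 / 2,188), the recovery experiment at 20 replicates of n=8,000, and
the truncation construction at n=2,188. The test suite uses n=200,000 for
the ground-truth monotonicity check, 200 random small cohorts (≤8 binary
predictors, n≤60) for the exhaustive-oracle equivalence of the CART
machinery, and reduced cohorts (n≈2,000–8,000) elsewhere; these sizes were
chosen so the statistical checks have adequate power at desk scale.

## Known limitations

- On the default synthetic cohorts the rule ensemble's greedy selection
  stops once adding any further elevated-risk rule would lower the 5:1
  score (around 93% outcome coverage); the separate 95% operating floor
  then admits only the all-positive threshold, so the ensemble survives
  the 90% screen with zero specificity and ranks last. This tension
  between the unconstrained selection objective and the floor is reported
  as-is rather than patched.

- Leaf risks of the frozen reference rule reuse this package's synthetic
  calibration; the original instrument's risks are published only
  graphically.
- The generator's joint predictor law is independence plus explicit
  redundancy pairs; models that exploit predictor interactions are
  exercised only weakly.
- The Brier score of class-weighted models reflects weighted risks (see
  above).
- Wall-clock timings are logged per stage (`timings.json`) for
  computability reporting but never asserted; they are hardware-dependent
  and excluded from the byte-identical determinism guarantee.
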