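# Methods

This package implements the full development-and-validation pipeline of a
clinical suspicion index for acid sphingomyelinase deficiency (ASMD,
Niemann–Pick disease types A, A/B and B): a symptom-based probability score
meant to flag, among patients who already show hepatosplenomegaly, those who
warrant confirmatory enzymatic/genetic testing. The pipeline runs from
chart-review cohorts (real or synthetic) through exact-test screening,
stability best-subset selection of an events-per-variable-capped multinomial
model, a prerequisite-gated score, and bootstrap/ROC internal validation.

## Study design being modelled

The development data are a retrospective chart review of 908 patients in
three groups: 48 confirmed ASMD cases, 52 controls (phenotypically similar
lysosomal disease: Niemann–Pick type C, Gaucher type I) and 808 non-cases
(ASMD excluded). Each chart records 27 binary signs/symptoms grouped by
organ system (neurological, visceral, skeletal) plus ASMD family history,
sex, age at symptom onset and age at data collection. The patient-level data
are not public; the package therefore ships the published per-group margins
(symptom counts, group sizes, demographic means/SDs) as its reference
configuration, and a seeded generator that emulates cohorts with that
structure.

## Synthetic cohorts

`simulate.generate` draws, per group, binary symptoms with the configured
prevalences. Within-patient dependence uses a single latent severity factor:
patient *i* has z_i ~ N(0,1), and symptom *j* in group *g* is Bernoulli with

    P(x_ij = 1 | z_i) = expit(alpha_gj + lambda * z_i)

where `lambda` (`dependence`, default 1.0 for the packaged study fixture,
0 for independent symptoms) is the shared loading and `alpha_gj` is
recalibrated by 80-node Gauss–Hermite quadrature and Brent root-finding so
the marginal prevalence equals the configured value to ~1e-12. The shared
factor induces positive pairwise association between all non-degenerate
symptoms within a group — the qualitative co-occurrence pattern of real
charts (isolated hepatomegaly without splenomegaly is rare in ASMD) —
while leaving the published marginals intact.

Ages are normal, truncated at zero, with the published per-group means/SDs;
onset ≤ current age is enforced by resampling offending pairs. Note the
published non-case demographics are internally inconsistent (mean onset
34.9 y exceeds mean current age 14.0 y); they are used as printed, so for
that group the constraint visibly distorts the realised age marginals. No
downstream computation uses non-case ages. Sex, family history and ASMD
subtype (B/AB/A at 30:16:2) are independent Bernoulli/categorical draws at
the published rates.

Reproducibility: one root seed; each group draws from its own substream
(SeedSequence spawn key), so resizing one group never perturbs another.

What the generator deliberately does not model: symptom onset timing and
progression, subtype-specific symptom profiles, arbitrary dependence
structure (one factor cannot encode, e.g., negative partial associations),
and any association between demographics and symptoms. Tests that pass on
these cohorts therefore validate the *pipeline*, not the clinical
performance of the deployed tool on real charts.

## Exact-test screening

For each catalogued symptom a cases-vs-comparator 2×2 table is built with
pairwise-complete denominators (unknown states excluded). The default
comparator is the control group: the published screening table's p-values
are incompatible with any contrast involving the 808 non-cases (e.g.
learning disability p = 0.14 despite 0/808 affected non-cases) and its odds
ratios match the cases-vs-controls conditional MLEs.

* **p-values** — Fisher's exact test, two-sided by the point-probability
  method (sum of hypergeometric probabilities of all tables, same margins,
  with point probability ≤ the observed one, 1e-7 relative tie margin).
  This is the convention of R's `fisher.test`, which the study used;
  scipy's implementation is used and is checked in the test suite against
  an exact integer-arithmetic enumeration for every table with n ≤ 60.
* **Odds ratios** — conditional maximum-likelihood estimates (the maximiser
  of Fisher's noncentral hypergeometric likelihood given all margins),
  oriented **comparator-odds / case-odds** to match the published table's
  direction; values below 1 mark case-enriched symptoms, the reverse of the
  conventional case-exposure OR. Boundary tables return exactly 0 or ∞,
  with a Haldane–Anscombe (+0.5) auxiliary estimate alongside; the
  published "0.01" entries in boundary rows are display artifacts, not
  estimates. The cMLE is checked against the conditional score equation
  (E_ψ[X] = observed count) and a grid+golden-section likelihood search.
* **Multiplicity** — Holm step-down adjustment over the testable symptoms.
  The model-candidate flag uses raw p < 0.001 by default (the adjusted
  value can be configured instead); 0.01 is also defensible from the study
  report, and is available via `ScreeningConfig.candidate_threshold`.

Reproduction notes (documented, deliberate): the published interstitial
lung disease row (p = 0.03, OR = 0.01) contradicts its own counts
(32/48 vs 3/52 → p ≪ 0.001, cMLE 0.032) and is excluded from reproduction
checks. Three rows printed "≤ 0.001" compute to 0.0014–0.0015, which round
to 0.001 at the table's three-decimal display precision; category checks
therefore match at display precision. The published muscular hypotonia OR
(1.50) is not reproducible from its counts by any standard estimator
(cMLE 1.5339, identical in R and scipy); the corresponding acceptance check
is expected to fail and the computed value is reported as-is.

## Risk model

A three-class multinomial logistic (single-layer softmax) model maps a
binary symptom pattern to probabilities of (case, control, non_case),
reference class non_case. The fit maximises the multinomial log-likelihood
minus a ridge penalty on slopes only:

    max_B  sum_i log P(y_i | x_i, B) - (r/2) * ||slopes||^2

* **Ridge default 1e-2.** Study-structured data are quasi-completely
  separated (mixed dyslipidemia in ~100% of non-cases, splenomegaly in
  ~0.4%); the unpenalised MLE diverges. 1e-2 keeps boundary coefficients
  finite while moving interior estimates negligibly (the test suite checks
  agreement with an unpenalised fit on separation-free data to <1e-5 in
  probability).
* **Optimisation.** Deterministic damped Newton from a zero start on data
  aggregated to unique symptom patterns with per-class counts (binary
  predictors make this exact and cheap: at most 2^k rows). Convergence at
  gradient max-norm < 1e-8; step-halving guarantees a monotone penalised
  objective; the objective is concave so no restarts are needed.
  Standard errors come from the inverse penalised observed information.
* **Missing predictors.** Complete-case: records with an unknown value in
  any model variable are excluded and counted.

## Variable selection

1. **Candidates** — symptoms with screening p below the threshold;
   hepatomegaly and splenomegaly are first merged into
   `hepatosplenomegaly` (AND rule under Kleene three-valued logic for
   unknowns; OR available). Family history is catalogued but is not a chart
   sign and never enters model candidacy.
2. **EPV cap** — at ≥10 events per variable, 48 cases admit
   floor(48/10) = 4 predictors. The cap is derived from the development
   cohort's event count; scaled synthetic runs keep the cap at 4 because it
   is part of the emulated study design.
3. **Stability selection** — per repetition (default 1000; 100 in the
   scaled test runs): a group-stratified 70/30 train/test split, an
   exhaustive enumeration of all candidate subsets of size ≤ 4 (793 fits
   per repetition at 12 candidates — no heuristic search), multinomial fit
   on train, criterion on test. The winner is the best test-set
   classification accuracy (test deviance is available; the choice of
   criterion is a documented assumption — none is named in the study
   report), ties broken toward smaller subsets then lexicographically.
   Variables in more than 70% of winners form the final set.
4. **Random-forest cross-check** — mean-decrease-in-impurity importances
   (scikit-learn) averaged over repeated stratified subsamples, as an
   independent ranking of the same candidates.

A closed-form check in the test suite computes, from the published
prevalences under independence, the *expected* test accuracy of every
4-subset of the screening candidates: the unique optimum is exactly the
published tool set {hepatosplenomegaly, thrombocytopenia with bleeding,
interstitial lung disease, mixed dyslipidemia with low HDL-C}. The
selection procedure's expectation therefore matches the published outcome.
However, the accuracy *margin* between that subset and its nearest
competitors is ≈4e-4 — about one patient in a ×10-scaled test split —
while the per-repetition sampling noise of test accuracy is several times
larger. Under independence at ×10 scale the per-repetition winners
consequently scatter among the near-tied top subsets and the weakest tool
variable (thrombocytopenia) stabilises near 30–50% occurrence rather than
above 70%. This is a property of the synthetic joint distribution, not of
the selection code; concentration above 70% requires either much larger
cohorts or the (unpublished) real-data dependence structure. The scaled
selection run is still executed and reported as measured.

## The deployed tool

`SITModel` wraps the fitted model with the audience contract:
hepatosplenomegaly is a **prerequisite** — without it the tool declines and
emits no probability at all (gate soundness is a tested invariant). For
gated-in patients the three inputs are entered as 0/1; the prerequisite
stays in the model as a predictor fixed at 1, so the model remains fittable
on full cohorts. The full 8-row probability chart enumerates all input
patterns. The high-risk cutoff defaults to 0.50 (the development workflow's
published median case score) and can be re-derived as the median case
probability among gated-in cases of a cohort.

On the synthetic fixture the derived cutoff lands near 1 rather than 0.5:
with marginal-matching simulation nearly every gated-in case carries at
least one positive input symptom, and any single positive input already
pushes P(case) above 0.9. The published 50% median implies a real-data
joint distribution with weaker co-occurrence between case status and the
score inputs than any marginal-preserving simulation reproduces. The
package reports the computed value; the deployment default stays 0.50.

## Internal validation

Two contrasts, as published: cases vs controls and cases vs non-cases.
Fixed-cutoff accuracy/sensitivity/specificity (score ≥ cutoff predicts
case) plus cutoff-free ROC curves; AUC uses the midrank tie convention and
equals the normalised rank-sum statistic (verified against an all-pairs
concordance oracle). Uncertainty from a stratified nonparametric bootstrap:
resample with replacement within each group (so the 48-case class cannot
vanish), refit on a 70% split of the resample, evaluate on the held-out
30%; percentile confidence intervals are order statistics of the
repetition distribution. Percentile rather than BCa intervals: the
simplest method consistent with the study's description. Repetitions whose
splits lose a class are redrawn and counted.

## Problem sizes and numerical choices

* Packaged study fixture: 908 patients (scale 1), dependence 1.0, seed 0.
* Scaled selection runs: 9 080 patients (scale 10), dependence 0,
  100 repetitions, subset cap 4 — about 1 100 exhaustive fits per
  repetition, a couple of minutes on one core thanks to the
  pattern-aggregation fit path.
* Exact-test oracle sweep: every 2×2 table with n ≤ 60 (≈6.3e5 tables),
  integer arithmetic throughout.
* Parameter-recovery simulation: 20 000 records, 3 binary predictors,
  slopes recovered within 3 SE.
* Degenerate inputs: zero-margin tables give p = 1 with a warning and an
  undefined (distinctly signalled) odds ratio; all-unknown symptom columns
  are flagged untestable and leave the Holm family; empty pattern cells are
  dropped from the aggregated fit; ties in best-subset accuracy resolve
  toward parsimony, then alphabetically.

## Known limitations

* The generator matches group-wise marginals and a one-factor dependence
  pattern only; real chart data have richer dependence, which is exactly
  where the synthetic results (cutoff level, fourth-variable stability)
  deviate from the published ones.
* The deployed web tool's fitted coefficients are unpublished; its exact
  probability outputs (e.g. the 42.48% worked example) are not
  reproducible and are covered qualitatively (orderings, high/low bands).
* No confounder adjustment (the study itself notes age as a likely
  confounder of lipid findings), no external validation, no calibration
  analysis.
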