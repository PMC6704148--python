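# Methods

This note documents the models, the synthetic data-generating process,
the numerical conventions and the design choices of the package. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic cohort model

The generator emulates the statistical structure of a population-based
primary breast-cancer RNA-seq cohort.

**Expression.** Each sample carries a latent molecular subtype drawn from
configurable proportions (defaults: LumA 0.45, LumB 0.20, HER2-enriched
0.12, basal-like 0.12, normal-like 0.11 — stated as approximations of a
typical population mix, not measured values). Four gene axes (ER
signalling, HER2 amplicon, proliferation, basal keratins; default
40/25/50/30 genes out of 500) are switched on or off per subtype: LumA =
ER; LumB = ER + proliferation; HER2-enriched = HER2 + proliferation;
basal-like = basal + proliferation; normal-like = none. Expression is
`baseline_g + axis_effect * activation + N(0, noise_sd)` on the
log2(FPKM + 0.1) scale; the 0.1 offset keeps zero-FPKM values finite and
is configurable. The per-gene baseline is drawn once from the seed, so
mean profiles, cohorts and the matching true-centroid model always agree.
Defaults `axis_effect = 2` (a 4-fold shift) and `noise_sd = 1` give
realistic overlap between subtypes; the planted-recovery tests use
`noise_sd = 0.5` (effect/noise = 4), at which nearest-centroid
classification recovers the generating subtype essentially perfectly.

**Clinical table.** Age is truncated normal (mean 65, sd 13, range
25–100 → median 65); tumor size is lognormal (median 17 mm, log-sd 0.55,
clipped to 1–126 mm); grade is drawn per subtype (LumA mostly 1–2,
basal-like mostly 3). ER IHC percent is drawn above 10% with a
subtype-conditional probability (LumA/LumB 0.98, normal-like 0.97,
HER2-enriched 0.72, basal-like 0.10). These conditional probabilities
*are* the IHC-vs-subtype discordance mechanism and were chosen so the
implied ER+ marginal equals the registry target 0.842 under the default
subtype mix; a separate `ihc_flip_prob` dial (default 0) adds symmetric
label noise on top when heterogeneity beyond the defaults is wanted.
HER2 positivity is likewise subtype-conditional (implied marginal
≈ 0.132). PR positivity depends on ER (0.87 | ER+, 0.04 | ER−).
Lymph-node status: 59% node-negative; positive cases get 1–3 nodes
(3/4 of them) or 4–12. Sub-micrometastases are encoded as node-negative
by default (their registry handling is not standardized; configurable in
stratification).

**Treatment.** Adjuvant regimens (endocrine only, chemotherapy (ACT)
only, endocrine+ACT, anti-HER2+ACT, anti-HER2+ACT+endocrine, untreated,
other) are sampled from registry-style percentage tables conditional on
the IHC marker group (ER+/HER2−/LN±, HER2+/ER±, TNBC). Assignment is
independent of outcome given the marker group — no confounding by
indication — which keeps the survival-recovery tests interpretable: a
fitted treatment effect in this cohort has nothing to recover, by
construction.

**Survival.** The latent risk is the cohort-standardized
proliferation-axis mean. Overall survival is exponential with hazard
`baseline_hazard * exp(log_hazard_per_risk_unit * risk)` (defaults 0.03/y
and 0.8) and administrative censoring at `followup_years` (default 8);
the event flag is 0 exactly when the horizon censors. The per-subtype
hazard structure is a free parameter of the generator, not an estimate of
any real cohort.

**What the generator does not emulate:** read-level count noise (the
noise is Gaussian on the log scale, not negative-binomial), gene–gene
correlation beyond the block axes, copy-number/mutation structure,
loss-to-follow-up censoring, and outcome-dependent treatment. Passing
tests therefore demonstrate the correctness and calibration of the
*pipeline machinery* on data with the assumed structure, not clinical
performance of any signature on real tumors.

## Signature model families

Models are external YAML artifacts (schema in `model_schema.md`); the
bundled sets are toys, self-consistent with the generator's axis
structure and clearly non-clinical. Five families:

* **centroid_subtype** — argmax over per-class correlations between a
  sample's profile and class centroids. Spearman by default for subtype
  calls (rank-based, robust to monotone distortions), Pearson for ROR
  correlation terms; both overridable per model. Ties break to the first
  class in declared order, deterministically.
* **module_subtype** — fixed decision tree over ER/HER2/proliferation
  module means: HER2 ≥ cut → HER2 class; else ER ≥ cut → luminal, split
  by the proliferation cut; else basal class.
* **linear_risk** — `intercept + sum_m beta_m * f_m` over module mean
  expressions, with optional per-module clip-at-zero
  (`max(f_m − tau_m, 0)`) mimicking recurrence-score forms, and an
  optional affine rescale of a declared raw range onto an output range
  (clamped at the ends).
* **ror** — `a * sum_k(w_k r_k) + b * P + c * size_mm/size_unit + const`,
  where `r_k` are centroid correlations and `P` the proliferation-module
  mean; variants S/P/T/PT/Tot enable terms; the Tot variant scores like
  PT and applies lymph-node-dependent cutpoints at risk assignment.
* **correlation_risk** — two-class call by correlation to a single
  good-outcome template: low risk iff correlation ≥ threshold.

**Reference-set centering.** Models may declare `centering:
reference_set`: the per-gene *median* over a reference subsample is
subtracted before correlation (median rather than mean for robustness).
The reference set is a seeded ER-stratified subsample (default 100
samples, 50% ER+), because published descriptions of
composition-controlled reference sets leave the exact stratification
open; the fraction is configurable.

**Risk assignment.** Scores map to ordered labels through strictly
increasing cutpoints; a score equal to a cutpoint takes the *higher*
class (right-closed upward). This boundary convention is documented
because the literature typically does not state one. Cutpoints may be
keyed by lymph-node status (`LN-`/`LN+`). Any NA input required by a
model yields an NA label — never silent imputation.

## Stratification

Nine clinical assessment groups from marker/treatment combinations
(TNBC ± ACT; HER2+/ER− and HER2+/ER+ with their standard regimens;
ER+/HER2− split by node status and endocrine ± ACT, plus untreated LN−),
with NONE as catch-all, so group assignment is a partition by
construction. ER/PR positivity is IHC strictly greater than 10% staining.
"Untreated" means all three adjuvant flags are zero; mixed or unexpected
regimens and NA markers/flags go to NONE.

## Concordance

Exact agreement is `100 * matches / n` on pairwise-complete samples
(NA handling is per comparison, not listwise across the signature panel —
this changes denominators and is therefore explicit). The
intermediate-omission variant drops every sample called intermediate by
either signature of a pair before counting; two-class signatures have no
intermediates and contribute all their samples. Agreement-chart geometry
follows the cumulative-marginal construction: class rectangles span the
cumulative row/column totals, the exact-agreement black square for class
k has side `count[k,k]` offset by the previous-level cell totals, and
gray zones span the within-one-level cells. Coordinates are emitted in
counts (origin bottom-left, axes 0..n) so the geometry is test-exact;
rendering merely scales. Chance-corrected statistics (kappa family) are
deliberately out of scope — the analyses report raw exact agreement.
Consensus voting calls a sample unanimous-low/high only when every
signature in the panel agrees; the default panel is all risk-prediction
signatures in the input table and is an argument, since any specific
published panel membership is a study choice.

## Survival analysis

Estimation is delegated to lifelines: product-limit Kaplan-Meier,
unweighted k-sample log-rank (chi-square, k−1 df), and Cox partial
likelihood with the Efron tie approximation (ties are certain with
registry-scale rounded follow-up; the choice is configurable nowhere
because Efron dominates Breslow at no cost). The Newton solver runs at
tightened precision (1e-9) so small worked examples match closed forms.
This package owns the design around the fits: per-class hazard ratios
against the signature's low-risk class (or the first class present);
multivariable adjustment for tumor size (mm), age, grade and binary
lymph-node status; grade enters categorically with grade 1 as reference
(an ordinal alternative is exposed via `grade_treatment="ordinal"`);
complete-case analysis with the dropped count reported; constant
covariates (e.g. LN in a node-homogeneous group) dropped automatically
with a note; classes below 8% of the group's non-NA calls excluded from
multivariable fits (a class at exactly 8% is retained — the rule is
"smaller than"); groups require ≥ 10 events by default (group exclusion
in real studies mixes size, events and demographic bias without a stated
cutoff, so the threshold is explicit and configurable here).
Non-convergence or separation is flagged in the result object, never
silent. The endpoint is a generic (time, event) pair labeled OS; no
competing risks.

## Problem sizes and calibration checks

The acceptance script and test suite compute, at these sizes chosen to
make sampling noise negligible relative to the tolerances: agreement
oracle equivalence on 1000 random tables (exact, tolerance 1e-12);
planted-subtype recovery at n=1000; log-rank type-I error over 1000 null
simulations of n=200 (expected in [0.035, 0.065] at alpha 0.05); Cox CI
coverage of a planted log-HR 0.69 over 100 replicates of n=2000
(expected ≥ 90); KM sup-distance to `exp(-lambda t)` at n=5000 (expected
< 0.03, the n=5000 Kolmogorov bound being ≈ 0.02); partition and
consensus-bound checks at n=2000 and 100 tables. Unit tests rerun the
stochastic calibrations at reduced replicate counts with loose bands;
the full-size runs live in the acceptance layer.

## Known limitations

Toy model parameters are not clinically meaningful and published
coefficient sets are not re-derived; single-sample rule-based subtype
predictors, integrative-cluster and TNBC-subtype classifiers trained on
external data are representable as configs only if their parameters are
transcribed; the generator's Gaussian expression noise understates
heavy-tailed count noise; and the survival module assumes proportional
hazards throughout (no time-varying effects).
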