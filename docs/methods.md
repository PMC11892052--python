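# Methods

## Scope and data model

The package implements a prescription-appropriateness analysis over two
linked sources:

1. a **drug-label knowledge base**: rows of (drug, clinical concept,
   relation ∈ {indication, contraindication}) plus a one-to-many concept →
   ICD-10-CM map. Every mapped code is truncated to its 3-character
   category and duplicates collapse, so the knowledge base is a pair of
   per-drug code sets. Concepts with no map entry are dropped, never
   guessed; the QC report counts them. Drug identity is at the
   active-ingredient level (lower-cased, whitespace-normalised names).
   Matching is exact at 3 characters — no hierarchy expansion beyond
   truncation.
2. a **survey data model** with four files (persons, conditions,
   prescription events, event–condition links), validated for referential
   integrity (every link endpoint exists and shares the prescription's
   person-year). Column names are remapped through a schema config so real
   public-use exports can be read without code changes.

Conditions default to *current only* (a condition is current when linked to
an event in the survey year); a flag widens matching to all recorded
conditions. Persons without prescriptions are retained in the data but drop
out of the analysis, which is defined over persons with at least one
in-scope prescription. Survey weights are read and carried but unused: the
prescription-level tables are unweighted counts. Prescriptions for drugs
absent from the knowledge base are excluded from all denominators
(`in_scope = 0`); a sensitivity flag counts them as off-label instead.

## Classification and aggregation

The four indicators are pure set algebra (see README), so classification is
deterministic and is tested record-for-record against an independent
nested-loop oracle, with the invariants `indic_narrow ≤ indic_broad` and
`indic_not_contra = indic_broad·(1 − contraindicated)` checked on every
record.

Prevalence tables report 100 × indicator means among in-scope prescriptions
per category of a grouping variable, and satisfy exactly the recombination
identity Σᵢnᵢpᵢ/Σᵢnᵢ = overall. Therapeutic-class tables order classes by
volume; empty class labels group under `unclassified`. The shipped
published reference rows are used only for internal-consistency checks of
this algebra (subgroup→overall recombination and the law-of-total-probability
mixture of contraindication rates by indication status); population
estimates themselves are not reproducible without the licensed extracts.

Median-split comparisons assign persons with the split variable exactly at
the median to the *low* group (≤ median vs >), compare outcome means with
Welch's unequal-variance t-test (the two-sample test is otherwise
unspecified in this literature; Welch is the conservative default), and
compare total expenditure as log(expenditure + 1) so zero spenders are
retained.

## Regression layer

All estimators share one design matrix: the two exposure fractions first,
then sex, single-year-of-age dummies, education, race, survey-year dummies,
one dummy per distinct prescription count up to a cap (default 30, pooled
above — "nonparametric in the count" without exploding the design),
centred mean approval year, and one dummy per condition category present in
the data. One reference level is dropped per categorical block; condition
dummies are non-exclusive indicators and all enter. Constant control
columns are dropped silently; a constant *exposure* raises an estimation
error, and residual rank deficiency raises an error naming the collinear
columns (located by pivoted QR).

- **LPM**: OLS with HC1 sandwich standard errors (the variance estimator is
  a package choice; the robust form is standard for linear probability
  models).
- **Probit**: ML probit reported as average marginal effects (overall
  dy/dx, delta-method SEs) so magnitudes are comparable to the LPM. Two
  numerical conventions matter with hundreds of sparse dummies: (i) dummy
  controls that perfectly predict the outcome in their on-group have an
  unbounded MLE and are dropped before fitting (the usual applied
  convention); (ii) Newton is warm-started from the LPM coefficients
  rescaled by 1/φ(Φ⁻¹(ȳ)), and a solution is accepted when the score has
  vanished even if the step-convergence flag oscillates. BFGS is the
  fallback, and an L1-penalised fit (reported without SEs, flagged in the
  result note) the last resort under separation.
- **DML (partially linear model)**: for each exposure *D* in turn (the
  other joins the controls), nuisance functions E[Y|X] and E[D|X] are
  learned out-of-fold with K-fold cross-fitting (default K = 5; K = 1 means
  an in-sample fit, which with a linear learner reduces exactly to
  Frisch–Waugh–Lovell partialled OLS — the correctness oracle). With
  residuals v = D − m̂ and u = Y − ℓ̂, θ̂ = Σvu/Σv² and the variance is the
  influence-function form Σv²ε̂²/(Σv²)²; with a fold seed fixed the output
  is bit-reproducible. If the residualised exposure is numerically constant
  the fold split is redrawn (up to 3 attempts). Default learners: 500-tree
  random forest (min leaf 5) or depth-8 regression tree; default seed
  20160101. Exposures are estimated one at a time because the orthogonal
  score is defined for a scalar treatment.

`mean_percentage` = 100 × estimate / outcome mean expresses every
coefficient as a share of the outcome's level; it is invariant to scaling
the outcome. Multiple outcomes are estimated independently with no
multiplicity correction.

## Synthetic-data generator

The generator emulates the *structure* the analysis assumes, with known
ground truth: Poisson-sized per-drug indication/contraindication code sets
distributed as concept pairs through a synthetic SNOMED-style map (each
category code gets one concept mapping to two full-precision codes);
persons with Poisson condition counts; zero-truncated-Poisson prescription
counts; and a prescriber that draws each prescription *indicated* with
probability `p_indicated_prescribing` (choosing a drug approved for one of
the person's conditions and linking it to that condition with probability
`p_link_narrow`) and otherwise uniformly from drugs not indicated for any
of the person's conditions. Contraindication status is never sampled — it
emerges from the overlap of the person's conditions with the drawn drug's
contraindication set, so the correlation between indicators is organic.
Ground truth is computed at generation time by direct set algebra and the
pipeline must reproduce it *exactly* (no sampling tolerance).

Binary outcomes use a clipped linear-probability link,
p = clip(α + β_contra·frac_contra + β_indic·frac_indic + Σ_c δ_c, 0.01, 0.99),
with per-condition effects δ_c ~ N(0, scale) drawn once per code — exactly
the confounding the condition-dummy block absorbs, so the LPM is correctly
specified and recovery tests are sharp. A logit link is available for
stress tests. Expenditure is log-normal and visit counts Poisson on the
same index.

What it does **not** emulate: real drug names or therapeutic taxonomies,
survey demographic marginals, longitudinal correlation across panels, or
reporting error. Passing tests therefore demonstrate correctness of the
algorithms under the stated generating process, not calibration to any real
population.

### Calibrated preset

`preset_paperlike` targets the headline mix of roughly 75% broad-indicated,
54% contraindicated and 33% optimal use. The calibration is analytic, not
fitted: with a 60-code universe, Poisson(4) conditions per person and
indicated-prescribing probability 0.764, the broad share is
0.764·P(K ≥ 1) ≈ 0.75, and the contraindication rate is the expectation of
the hypergeometric overlap probability over the Poisson condition-count and
contraindication-set-size laws (`expected_rates`), which fixes the per-drug
contraindication density at 11.7 for a 54% rate. The narrow-link
probability 0.75 puts narrow-indicated use near 56%. A single realised drug
universe adds cluster noise of order 1–2 pp around these expectations.

### Study conditions for the simulation studies

The effect-recovery study plants β_contra = +0.04 and β_indic = −0.03 on a
binary limitation outcome and runs 100 replicates at n = 5000 persons. The
remaining knobs are chosen for identification, once: mostly
single-prescription persons (zero-truncated Poisson rate 0.5) and a
balanced indicated share (0.5), so the exposure fractions carry close to
the maximal variance a [0, 1] variable allows; and a low-prevalence outcome
(α = 0.10), whose Bernoulli noise floor √(p(1−p)) leaves the planted betas
several standard errors from zero. Under these conditions the LPM/probit
CIs cover the truth at their nominal rate and the qualitative sign pattern
(contraindicated harmful, indicated beneficial) resolves essentially
always.

The DML study uses a separate partially linear DGP with smooth nonlinear
confounding (sin and quadratic transforms shared by the exposure and
outcome equations, θ = 0.5), n = 2000 per replicate and 100-tree forests —
sizes at which a full study runs in a few minutes on one CPU while the
naive linear fit is badly biased (≈ +0.36) and cross-fitted DML removes
essentially all of it with near-nominal CI coverage.

## Known limitations

- Age-, dose- and route-specific label restrictions, and drug–drug
  interaction contraindications, are out of scope: matching is drug ×
  disease-category only.
- The probit's perfect-predictor dummy dropping slightly changes the
  control set relative to the LPM in sparse samples.
- Estimates are adjusted associations; no causal identification is
  claimed, and survey-design variance (weights, strata) is not used.
- How many-to-many map rows with map-rule qualifiers should be filtered is
  unspecified upstream; all rows are ingested.
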