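# Methods

This note documents the statistical model behind `langscreen`, the
design choices where several defensible options existed, and what the
synthetic-data results do and do not establish.

## The screening problem

A two-stage screen for significant language deficits (SLD) at age 3,
administered at the age-2 well-baby check-up: stage 1 is parent report
(a 37-item expressive-vocabulary word list scored 0–37, a
two-word-combination item, a parental-concerns item), stage 2 a 9-item
word-comprehension subtest administered by the pediatrician only to
stage-1 failures.  The outcome is binary SLD one year later, defined by
a −1.5 SD rule on a reference language measure.  Both stages are scored
as fitted logistic SLD probabilities; the composite score uses the
stage-1 probability for passes and the stage-2 probability for
failures, so it refines the ranking exactly where the extra assessment
was made.

## Generative cohort model

Because validated cohorts of this kind are not publicly deposited, the
package ships a generative stand-in with the following structure:

* **Latent abilities.** Age-2 ability `L2 ~ N(0,1)`; age-3 ability
  `L3 = rho*L2 + sqrt(1-rho^2)*eps` with `eps ~ N(0,1)`.  The default
  stability `rho = 0.6` encodes the well-replicated instability of
  early language trajectories (roughly half of late talkers reach the
  normal range by age 3–4).  A consequence worth knowing: with
  `rho = 0.6` no age-2 screen, however good, can exceed an AUC of
  roughly 0.81–0.86 for the age-3 outcome, so simulated accuracies sit
  slightly below the strongest published figures for instruments of
  this type.
* **Outcome.** `sld = L3 < Phi^-1(p)` with default prevalence
  `p = 0.113`, the analysis-sample rate reported for the screen this
  design follows (its full-sample rate was 9.1%; the analysis sample is
  what the validation statistics condition on, so it is the default).
  A literal Gaussian −1.5 SD rule would imply 6.7%; calibrating the
  quantile to the observed prevalence reproduces the base rates that
  every downstream PPV/DLR computation depends on.
* **Bounded count scores.** `vocab ~ Binomial(37, sigmoid(a_v + b_v*L2))`
  and `comprehension ~ Binomial(9, sigmoid(a_c + b_c*Lc))`.  Intercepts
  and slopes are calibrated by 61-node Gauss–Hermite quadrature so the
  population mean/SD hit their targets exactly in expectation
  (comprehension 6.86 / 1.80 as reported for the instrument; vocabulary
  20 / 9 on the 0–37 scale — no published marginal exists for the short
  word list, and this choice mirrors roughly half the list being in use
  at 24 months with strong ability-driven overdispersion).  An optional
  `overdispersion` knob adds extra per-child logit noise (off by
  default; marginal calibration assumes it is off).
* **Comprehension taps persistence.** The direct assessment loads on
  `Lc = (L2 + w*eps)/sqrt(1+w^2)` with default `w = 0.5` rather than on
  `L2` alone.  Receptive language is assessed directly and taps a
  dimension of risk the parent-reported expressive measures cannot see;
  statistically this is what makes stage 2 genuinely informative.
  Under a strict one-factor model (`w = 0`), the 37-item word list
  nearly exhausts the usable age-2 signal, stage 2 adds almost nothing,
  and the empirical hallmarks of this design — word comprehension
  carrying the largest standardized stage-2 coefficient, and a real
  two-stage AUC gain — cannot arise.  `w` is a loading like any other
  (`loadings["comprehension_direct"]`) and setting it to 0 restores the
  one-factor structure.
* **Binary flags.** `no_two_word` and `parental_concerns` are Bernoulli
  with logits linear in `L2` (loadings −2.5 and −2.0; intercepts
  calibrated to the 5.6% and 12.4% population rates).  The strong
  loadings reflect that both items are direct parental judgements of
  the child's language and make their conditional association with the
  outcome — given the word list — strong enough to survive variable
  selection at realistic sample sizes, mirroring the published
  stage-1 model.
* **Sociodemographics.** Age in months on {23, 24, 25} (matching mean
  23.92, SD 0.972 — the SD forces most mass to the endpoints), sex
  (51.8% male) and a four-level parental-education factor (1.4 / 47.0 /
  25.8 / 25.8%) are drawn independently of ability.  They are
  deliberate null predictors: variable selection should discard them.
* **Reference scales.** `ref_vocab_z`, `ref_grammar_z` are
  `lam*L3 + sqrt(1-lam^2)*noise` with `lam = 0.9`, unit-variance by
  construction; they exist to validate risk tiers by group comparison.
* **Word-list item matrix.** Item endorsement is Bernoulli with
  `P = sigmoid(1.3*(L2 - d_j))`, difficulties `d_j` spread as scaled
  normal quantiles so that any usage threshold bites somewhere.  The
  item generator draws `L2` as its first variate from the seeded
  generator, so its rows align child-for-child with a cohort generated
  from the same config.

What the simulator does **not** model: multilingual-exclusion
logistics, clustering of children within pediatric practices,
questionnaire non-response, and any non-monotone or multi-factor
structure among the parent-report items.  Passing tests on this
generator therefore demonstrate that the *machinery* is correct and
that the construction behaves as designed under a plausible data model
— not that any particular accuracy level will be attained in field
data.

## Staged model fitting

Logistic models are fitted by Newton/IRLS maximum likelihood
(tolerance 1e-8, 100 iterations; standard errors from the observed
information).  Complete separation is detected by a per-column screen
and reported as an error naming the predictor; quasi-complete
separation is flagged when an estimate diverges (|b| > 20) or the
information matrix is singular at the optimum.  The package does not
fit penalized (Firth) regression; the error message suggests it.

Backward elimination removes, at each step, the model term with the
largest likelihood-ratio p-value above `removal_alpha`; a multi-column
categorical factor (education) is one term with a joint multi-df LR
test.  `removal_alpha` defaults to 0.10, the stepwise-removal
convention of the major commercial package for this analysis style; the
threshold is a free parameter.  A term whose ML estimate diverges
(e.g. a rare education category with no outcome events in a small
cohort) can be kept in no model and is removed immediately with a
logged reason — the pragmatic choice every applied workflow makes.
Note the inherent property of LR-based stepdown: each null term is
falsely retained with probability ≈ `removal_alpha`, so with three null
terms the default threshold leaves some null in the model in roughly a
quarter of cohorts; the selection-consistency tests therefore run the
sharp-threshold variant (`removal_alpha = 0.005`) where joint removal
is near-certain, and separately confirm signal retention at the
default.

Standardized coefficients are `b_j * SD(x_j)` (x-standardization,
sample SD); a latent-outcome variant dividing additionally by
`sqrt(var(Xb) + pi^2/3)` is available (`method="latent"`).  Nagelkerke's
R² normalizes Cox–Snell's `1 - exp((2/n)(LL0 - LLm))` by its maximum
`1 - exp((2/n)LL0)`.  Wald odds-ratio CIs use full-precision b and SE;
recomputation from printed (rounded) coefficients can differ in the
last digit.

## Cutoffs, tiers and accuracy statistics

Orientation: **positive = score ≥ cutoff** everywhere, including
exactly at the boundary (the convention must be fixed somewhere; ≥ is
applied consistently and tested).  Candidate cutoffs are midpoints
between adjacent distinct observed scores plus ±∞, which removes
dependence on arbitrary observed-value boundaries.

* Sensitivity-targeted search: choose the candidate whose Se is
  *closest* to the target; ties broken by higher Sp, then the higher
  (more conservative) cutoff.
* PPV-targeted search: among candidates with PPV ≥ target, maximize Se;
  ties broken by the lower cutoff.  If the target is unattainable the
  max-PPV cutoff is returned with `target_met=False` — fixing PPV and
  reporting the resulting Se is how high-risk tiers are defined in this
  design.

Proportion CIs are Clopper–Pearson (exact binomial); DLR CIs use the
log method (delta-method SE `sqrt(1/a - 1/m + 1/b - 1/n)` on the log
ratio).  The published reports this package mirrors do not state their
CI methods and print at least one internally inconsistent interval, so
CI agreement with such sources is not expected beyond magnitude.
Zero-denominator statistics are reported as undefined-with-reason
rather than NaN.

Risk tiers: high iff `total ≥ cut_high`, moderate iff
`cut_moderate ≤ total < cut_high`, else low.  The tier summary reports
counts, tier prevalence and stratum-specific likelihood ratios
(tier share of affected ÷ tier share of unaffected).  When a flow
report gives a specificity, the denominator is all unaffected children;
screen-negative counts are reported separately (published flow texts
sometimes mix the two denominators).

## Paired ROC and group inference

AUC is the Mann–Whitney pair-counting estimator with ties counted ½,
computed through DeLong placement values (mean placement = AUC to
machine precision, which the tests assert at 1e-12).  Variances and the
paired ΔAUC z-test use the placement covariance; CIs are normal on the
AUC scale, clipped to [0, 1].  The bootstrap paired test resamples
children with replacement *within* the affected and unaffected strata
(every replicate keeps both classes), recomputes ΔAUC per replicate,
and refers `D = ΔAUC / SD_boot(ΔAUC)` to a standard normal; the default
is 2,000 replicates and a seed is mandatory.

McNemar's test uses `(b-c)^2/(b+c)` without continuity correction;
the exact two-sided binomial p-value `2·P(Bin(b+c, 1/2) ≤ min(b,c))`
(capped at 1) is reported alongside whenever `b+c < 25`.  All p-values
in the package are two-sided.

Welch's ANOVA uses the standard heteroscedastic F with
Welch–Satterthwaite fractional denominator df; η² is the classical
between-over-total sum of squares on the pooled data (the variant is
unstated in the sources this mirrors; the classical one is the common
default and is documented here).  η² and the Welch F answer different
questions (effect size vs heteroscedasticity-robust inference) and are
reported together.

## Pipeline conventions

* Records missing stage-1 predictors or the outcome are dropped with a
  logged count; stage-1 failures missing the word-comprehension score
  are dropped likewise.  Comprehension is never read for stage-1
  passes, so a protocol-faithful cohort (comprehension only measured on
  failures) yields byte-identical results to a fully measured one.
* Stage 2 is fitted on stage-1 failures only (`fit_stage2_on="all"`
  exists for sensitivity analysis).  Fewer than 10 outcome events among
  failures aborts with a diagnostic (exit code 3 in the CLI).
* The stage-1 cutoff is recomputed per dataset by default;
  `freeze_stage1_cutoff` pins it (e.g. at a published 0.05) for
  scoring under frozen coefficients.
* One integer seed drives the generator, the bootstrap and nothing
  else (all other computation is deterministic); a seeded report is
  byte-reproducible, which the tests assert on the serialized JSON.

## Problem sizes used in validation

Generator calibration is checked at n = 100,000 (binomial SE ≈ 0.001 on
the prevalence), parameter recovery and the AUC-dominance property at
n = 20,000, selection consistency on 100 replicates of n = 3,000 with
outcome effect sizes set to the published stage-1 coefficients, and the
DeLong null calibration on 200 replicates of n = 600.  These sizes make
the statistical properties sharp while keeping the full suite fast.

## Known limitations

* No Firth/penalized fallback under separation; rare-category terms are
  removed rather than shrunk.
* The bootstrap D-test assumes approximate normality of the bootstrap
  ΔAUC distribution; no BCa or percentile variant is offered.
* No partial AUC, ROC smoothing, covariate adjustment, or
  cost-weighted/Youden cutpoints — the two constrained searches above
  are the design's decision rules.
* The simulator's single-latent structure (plus the one receptive
  mixing weight) is the simplest model consistent with the design's
  empirical hallmarks; it will understate predictor-specific residual
  structure present in real cohorts.
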