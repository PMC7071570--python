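# Methods

This note records the models, defaults and numerical choices behind
`emrsmoke`, and what the synthetic validation does and does not
establish.

## The classifier

Each risk-factor record carries three free-text fields. The classifier
normalizes text (lowercase, trimmed, internal whitespace collapsed,
accents preserved for bilingual lexicons) and matches an ordered,
per-category pattern lexicon with **letter-only word boundaries**:
`ppd` fires inside `2ppd` (digit-adjacent quantity phrases are common),
but `no` does not fire inside `non`. Regex `\b` would get the first case
wrong.

Decision procedure, per record:

1. **Guard.** A field containing a kinship term (aunt, father, husband,
   ...) is family-history text and is nullified — the *field*, not the
   whole record, so usable information in other fields survives. This is
   the conservative reading of "entries containing relationship words
   are ignored".
2. **Intra-field resolution.** Cessation/negation wording routinely
   modifies an affirmative mention in the same field ("ex-smoker",
   "smoker: quit", "non-smoker"). A match for `current` is therefore
   suppressed whenever `past`, `never` or `not_current` also matched the
   field. Conflicts *among* the cessation categories ("never smoked,
   quit 2010") still resolve to `unknown`. A pure longest-match rule was
   considered and rejected: it handles "ex-smoker" but classifies
   "smoker: quit" as current, which is wrong.
3. **Precedence.** Fields are evaluated Status → Value → Name. The first
   field resolving to exactly one category fixes the status; a field
   resolving to two or more fixes `unknown` and stops; all-empty yields
   `unknown` with `decisive_field = none`. When two fields would have
   produced different single categories (Status "Current" vs Value "non
   smoker"), the higher-precedence field wins and `conflict_flag` is set
   for audit — such records correspond to the reference-review category
   "conflicting information", and the classifier still emits a status
   for them.
4. **Per-patient resolution.** The most recently dated record wins;
   undated records sort before dated ones; date ties prefer an
   informative (non-unknown) status and then input order.

The shipped lexicon is an **approximation**: the production lexicon it
stands in for was derived from manual review of a proprietary database
and never published. The algorithmic contribution is the
precedence/guard/conflict machinery; the lexicon is configuration
(`data/default_lexicon.yaml`, YAML, one block per category).

## Cohort derivation

Filters apply in order — hypertension flag, not deceased/inactive, at
least `min_encounters` distinct encounter dates in the two-year window
(2016-07-01 to 2018-06-30; the sensitivity setting is 3) — and the flow
counts conserve: input = excluded (summed over steps) + cohort.

* **Rurality**: rural iff the second postal-code character is `0`, urban
  iff any other digit, missing otherwise.
* **BMI cleaning**: values outside 12–70 kg/m² dropped, then a forward
  scan drops any value differing by more than 10 kg/m² from the last
  *retained* value. Keeping the earlier retained value (rather than
  either member of a violating pair) prevents one outlier from
  cascade-dropping valid data. The most recent retained value enters the
  cohort table.
* **Encounters**: distinct dates (same-day visits count once); the
  window-restricted count drives the activity filter, the full-history
  count is the descriptive variable.
* **Age** is computed at the window end (2018); no finer reference date
  is defined for this cohort.
* **Recode**: patient-level `unknown` and `not_current` become missing
  before imputation. `not_current` cannot be distinguished from past or
  never, and the imputation categories are exactly
  {current, past, never}.
* **Group comparisons** (recorded vs missing smoking): chi-squared for
  categorical variables, Welch's two-sample test for continuous ones
  (the generic "one-way test" is otherwise underspecified), Wilcoxon
  rank-sum for the skewed encounter counts. Degenerate groups report NA
  with a reason rather than a spurious p-value.

## The imputation engine

Chained equations over the incomplete variables (smoking, BMI, systolic
BP), visited in order of ascending missingness. Missing cells are
initialized by draws from observed margins; each of `iterations` sweeps
(default 5) refits each variable's conditional model on the current
completed data; `m` copies (default 40) are produced.

* **Smoking** — multinomial logistic regression on sex, age, rurality,
  BMI, systolic BP, diabetes, encounter count and EMR vendor
  (standardized continuous predictors, dummy-coded categoricals).
  Parameter uncertainty is propagated per draw, either by **bootstrap
  refit** (default) or by a **normal-approximation posterior draw** of
  the coefficients (`mi_param_draw="posterior"`, via statsmodels
  MNLogit). Bootstrap is the default because the Hessian-based normal
  approximation fails on quasi-separated data, which synthetic worlds
  with strong covariate effects produce routinely; both routes
  demonstrably yield positive between-imputation variance (tested — the
  classic failure mode is fitting once and drawing m times, which
  collapses it).
* **MNAR restriction** (`mnar_no_current`) — the smoking model is fitted
  only on observed past/never patients (a binary problem) and missing
  cells are drawn from {past, never}. Requires at least one observed
  patient in each of the two categories; the post-imputation current
  count is exactly the observed count on every copy, which is asserted
  at run time.
* **Continuous auxiliaries** — type-1 predictive mean matching with 5
  donors: Bayesian coefficient draw (scaled-inverse-chi-squared variance,
  normal coefficients), donors located by the ML predictions, targets by
  the drawn coefficients, one of the 5 nearest donors' observed values
  handed back. Ridge jitter of 1e-8 on the normal equations guards
  against collinear designs.
* **Degenerate cases** — a single observed class, a pathological
  bootstrap resample, or a failed fit fall back (in that order) to fits
  on the original rows and finally to margin draws, each with a logged
  warning on the stack.
* **Not modelled** — rurality's `missing` level is kept as its own dummy
  level rather than imputed; missing sex is mode-filled with a warning
  (it is vanishingly rare in the motivating data). Free-text strings are
  never predictors. COPD is not a default predictor but any predictor
  list can be passed explicitly.

**Pooling.** Per-category proportions average over copies; within
variance is the mean of p(1−p)/n, between variance the sample variance
of the per-copy proportions, total `W + (1 + 1/m)B`.

**Injection simulation.** Given a smoking-complete cohort, mask an exact
uniform-random fraction (default 40.8%), re-impute, pool, and report the
per-category error. The error is reported both as a percentage-point
difference (the headline reading) and as a ratio in percent, since the
printed precision of the motivating figures does not disambiguate the
two. At study scale (n = 28,634 complete cases, m = 40, 5 iterations,
seed 314) the suite measures errors of +0.04, −0.14 and +0.10
percentage points for current/past/never — the same order of magnitude
as the published small relative errors.

## The synthetic world

Defaults are the stated study conditions wherever a value is printed:
truth proportions 21.2 / 22.7 / 56.2 (current/past/never; intercepts of
the covariate-dependent multinomial are calibrated by iterated
proportional adjustment so these are the *expected marginals*, not just
base rates), vendor mix 54.5 / 42.6 / 1.0 / 0.7 / 1.3 % and per-vendor
recording probabilities 0.777 / 0.363 / 0.970 / 0.255 / 0.230
(Wolf / Med Access / Practice Solutions / Telin / Healthquest), age
65 (SD 14), 51% female, BMI 31 (SD 7), systolic BP 133 (SD 16),
diastolic 79 (SD 11), diabetes 27%, COPD 10%, ~24% rural, 1.8% missing
postal codes, ~20% of recorded patients with more than one smoking
record.

Values no source states were chosen once as field-plausible and are not
revisited: covariate effects on smoking (log-odds vs never — current:
+0.5 male, −0.3 per decade over 65, +0.8 COPD; past: +0.3 male, +0.3 per
decade, +0.5 COPD), encounter counts 1 + negative binomial (r = 2, mean
≈ 30), BMI missing 10%, BP missing 1%, deceased 2%, inactive 3%, 4%
without an in-window visit, and distractor rates (2% kinship, 0.5%
conflicting, 3% multi-risk-factor, 1% non-smoking, 1% "non-smoker"
phrasing).

Missingness mechanisms are generative and checkable: `mcar` masks
uniformly; `mar_covariate` masks with vendor-based probabilities tilted
by age on the logit scale (independent of truth given covariates — a
property the tests verify by stratified chi-squared); `mnar_status`
masks at per-status rates, with current smokers retained by default (the
MNAR assumption made generative).

**What a green test establishes.** The closed loop (distractor-free
templates drawn from the default lexicon → classification reproduces
truth exactly) validates the classification *machinery*, not the
lexicon's coverage of real clinical text: real extracts contain phrasings,
typos and French text the default lexicon does not know. Likewise the
MAR recovery test shows the engine is unbiased under the stated
mechanism at the stated scale; it cannot certify behaviour under real,
unknown missingness. Vendor dialects are synthetic stand-ins; the real
vendors are known to differ hugely in completeness but their actual text
conventions are not public. No longitudinal quit/relapse dynamics, no
realistic postal-code geography beyond the second character, no French
defaults (the lexicon format supports them).

## Numerical and reproducibility notes

* All randomness flows through `numpy.random.Generator` seeded from the
  scenario/config; the full pipeline is byte-deterministic for a fixed
  seed (tested).
* Logistic fits use scikit-learn (lbfgs, C = 100) — mild regularization
  keeps quasi-separated bootstrap resamples finite without materially
  biasing proportions at cohort scale.
* Confusion matrices have five predicted rows and seven reference
  columns; `conflicting` and `not_smoking_related` are review-only
  columns with no diagonal partner, counting only against accuracy
  denominators.
* The survey benchmark (current 18.9 [14.8–22.9], past 21.1 [17.0–25.1],
  never 60.1 [55.2–65.0] %) is a fixed external constant; the CI check
  is a point-in-interval flag, not a formal test.

## Known limitations

* The default lexicon is English-only and deliberately small; accuracy
  on real extracts is bounded by lexicon coverage.
* The imputation engine handles exactly the variable types this pipeline
  needs (unordered categorical, continuous via PMM); it is not a general
  chained-equations clone.
* `not_current` is recoded to missing before imputation; if those
  patients are systematically former smokers this discards a little
  information (they are ~1% of patients in the synthetic default).
* Proportion pooling treats each copy's proportion as the statistic of
  interest; no logit transform is applied before Rubin pooling, which is
  adequate away from 0/1 but not for rare categories.
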