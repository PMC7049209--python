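# Methods

## Problem and model

A patient with aneurysmal subarachnoid hemorrhage and k ≥ 2 intracranial
aneurysms has exactly one bleeding source. The package models the rupture
label of each aneurysm as a binomial outcome with logistic link,

η = β₀ + β_size·size + β_loc(region) + β_shape·1[irregular]
  + γᵀ(age, smoker, hypertension, aneurysms per patient,
       additional aneurysms in the same region) + b_patient,

where the five location regions are AcomA/ACA (reference), PcomA, posterior
circulation, MCA, and ICA without the PcomA segment; shape is regular vs
irregular (lobulated or bleb-bearing, regular as reference); and b_patient is
a patient-specific random intercept accounting for within-patient dependence.
The aneurysm-specific part (size, location, shape) is the **prediction
score**. Because the patient-specific part and b are constant within a
patient, the within-patient argmax of the score equals the argmax of the
predicted rupture probability: the score is identified, and meant to be used,
only up to within-patient comparison. No clamping or intercept is applied to
the reported score; AcomA/ACA and regular shape pin the zero point.

## Fitting: component-wise gradient boosting

The model is fitted by functional gradient descent on the binomial deviance
(outcome coded 0/1, negative gradient y − p):

1. initialize the additive predictor at the empirical log-odds of rupture;
2. fit every candidate base learner to the current negative gradient by
   (penalized) least squares: one simple linear learner per covariate (slope
   through the covariate centered on the training sample; each location dummy
   is individually selectable) and one ridge-penalized patient-intercept
   learner whose penalty is solved by bisection so that its effective degrees
   of freedom Σ n_g/(n_g+λ) equal a configured value (default 4);
3. update only the component with the smallest residual sum of squares,
   damped by the step length ν (default 0.1);
4. stop after m_stop iterations.

Early stopping is the regularizer and the variable selector: a covariate
never selected keeps coefficient exactly 0. m_stop is tuned by patient-level
ten-fold cross-validation (patients, not aneurysms, are held out; fold sizes
differ by at most one; deterministic given a seed), minimizing mean held-out
deviance over the iteration path; unseen patients get a zero random
intercept. Nested evaluation re-tunes m_stop inside every outer learning
sample, so no held-out patient influences any training decision.

Score extraction is exact: on the raw covariate scale the location-dummy and
shape-dummy coefficients *are* the offsets against the reference levels, and
the centering constants are absorbed into the intercept, which (like all
patient-level terms) cancels in the within-patient ranking.

A `single_learner` mode replaces component-wise selection with one joint
least-squares learner over all candidates plus a free intercept. Its fixed
point solves the logistic score equations, so the path converges to the
maximum-likelihood fit; the test suite uses this as a dual-route check
against an independently coded IRLS fit (statsmodels), with component-wise
selection checked separately at 5% relative tolerance on the dominant
coefficient. Degenerate inputs: an all-0 or all-1 outcome is refused; a
constant covariate gets slope 0 and can never be selected; ties in the RSS
comparison resolve to the first candidate in declaration order
(deterministic); no special treatment of separation — the m_stop cap is the
guard.

Whether covariates should be centered or standardized before boosting is not
externally fixed; this implementation centers (which changes the selection
path relative to standardizing, but not the extracted raw-scale score of a
converged fit) and documents rather than resolves the difference.

## Shape imputation

Shape is the only field allowed to be missing. Missing shapes are filled by a
single (not multiple) logistic regression of irregular-vs-regular on all
other variables — size, location dummies, the rupture outcome, and the
patient covariates — fitted on complete cases (unpenalized,
scikit-learn). Assignment is deterministic: irregular iff fitted probability
≥ threshold (default 0.5); no stochastic draw, so imputation is reproducible
and the reported imputed counts are exact. Preconditions: complete cases of
both shape classes; missingness anywhere else is refused.

## Evaluation

Patient-level accuracy: a patient counts as correctly classified when the
within-patient argmax of the extracted score finds the true bleeding source.
Tie policy (ties are exact-equality events on unrounded scores):

- `non_strict` (default): a patient is correct when the ruptured aneurysm is
  *in* the argmax set. This is the only reading consistent with the
  prospective cohort, which contains a patient with two identical 5 mm
  regular MCA aneurysms (an exact tie) counted as correctly classified.
- `first`: resolve to the first argmax member in table order. Used for the
  null-calibration check, because under a zero-signal generator the boosted
  score can shrink to all-zero, making every patient an all-way tie that
  non-strict counting would score as correct; `first` has exactly 1/k hit
  probability under the null.
- `error`: raise on ties.

Accuracy is reported overall and stratified by aneurysm count k against the
random-guessing baseline 1/k; the overall rate is the count-weighted mean of
the stratified rates. Aneurysm-level discrimination is the rank-based
(Mann–Whitney, ties one-half) AUC of predicted probabilities, reported as the
unweighted mean over folds (pooled-prediction AUC is also computed), on
held-out patients without random effects and on training patients with them,
plus a complete-data fit. Note that under the null the *aneurysm-level* AUC
sits above 0.5 whenever aneurysm count varies: the count alone predicts the
marginal 1/k rupture rate; the patient-level accuracy is the null-calibrated
quantity.

Calibration: fitted probabilities are sorted and split into ⌊n/50⌋ intervals
of 50 with the remainder appended to the last interval (this remainder rule
is as specified even though it makes the interval count depend on n), per
interval reporting mean predicted probability, observed rupture frequency and
count. For calibration *testing* on synthetic data at n = 5000 the package
uses 500–1000 observations per bin: with bins of 50 the per-bin binomial
noise (~0.07 SD) would exceed any meaningful discrepancy bound.

## Synthetic cohorts

The generator emulates the derivation-cohort structure: 252 patients by
default with aneurysm counts drawn from weights {2: 174, 3: 49, 4: 22, 5: 6,
6: 1} (expected total 619 aneurysms), locations from weights {AcomA/ACA 119,
PcomA 85, posterior 72, MCA 234, ICA 109}, irregular shape with probability
107/619, sizes log-normal with median 6 mm and σ_log = 0.6238 (solving
SD ≈ 5 mm for the reported "6 ± 5" summary; the summary does not name a
distribution, so a right-skewed positive law with matching median and spread
is the modeling choice), truncated at 40 mm by rejection; age normal
(53, 12.8) truncated positive, hypertension 0.44, smoking 0.35.

The one-rupture-per-patient invariant holds by construction: the ruptured
aneurysm is drawn from a within-patient conditional logit with utilities
`signal_scale × score(truth) + N(0, random_effect_sd)`. Patient-level terms
cancel in this conditional model; `signal_scale = 0` reduces exactly to
uniform 1/k guessing and large `signal_scale` concentrates the rupture on the
argmax-score aneurysm. Patient covariates are generated but carry no effect
under the default truth (the published score has none); the truth
coefficients are configurable to exercise the selector. Generation is
bit-reproducible given the seed.

What the generator does *not* emulate: imaging/hemorrhage patterns, treatment
pathways, covariate correlations (e.g. smoking–hypertension), informative
missingness (shape masking is completely at random), or any marginal-model
misspecification present in real data. Passing recovery and evaluation tests
on these cohorts therefore validates the pipeline's machinery, not the
clinical transportability of the score.

One identifiability consequence matters for parameter recovery: fitting a
*marginal* aneurysm-level logistic model to conditional-logit data recovers
the generating utilities only up to attenuation, and the attenuation is not
perfectly uniform across coefficients. Recovery is therefore judged on signs,
on the ordering of the location offsets, and on within-patient rank agreement
(which converges to 1 as n grows), not on absolute coefficient error. At the
recovery scale used in testing (n = 2000 patients, signal ×3) the PcomA
offset (true −0.0104) remains below its sampling noise (empirical SD ≈ 0.07):
its estimated sign is essentially random, and seeded runs can place it
slightly positive. The recovery experiment restricts candidates to the
aneurysm-specific covariates: the aneurysm-count covariates genuinely carry
competitor-strength information correlated with location and would otherwise
bias the extracted pure-location offsets.

## Packaged prospective cohort

The 34-patient / 83-aneurysm prospective validation cohort is shipped as a
CSV fixture (one row per aneurysm; fine-grained site, pooled region, size,
shape, treatment, the printed reference score, and the bleeding-source label
— surgical inspection where performed, expert/bleeding-pattern validation
otherwise; patient covariates were not published and are NA). Three printed
reference scores are misprints: the PcomA 6 mm regular row of patient 2
prints 0.0216 where the coefficients give 0.2458 (confirmed by the identical
covariates of patient 4's irregular counterpart), and the two 3 mm posterior
regular rows print −0.0556 and −0.0557 — two different values for identical
covariates, so no coefficient set can match both; every other posterior row
is consistent with −0.0550. The misprints do not affect any within-patient
ranking. Patient 24 is flagged: the surgically confirmed source (MCA 10 mm
regular, score 0.0215) scores below the basilar-tip aneurysm (0.6118), so the
honest prospective tally is 33/34 by score argmax; the package reports the
per-patient breakdown instead of asserting a perfect score. Comparisons to
printed values use round-half-away-from-zero at 4 decimals; internal
arithmetic is never rounded.

## Problem sizes and defaults used in testing

Test and acceptance runs use cohorts of 80–2000 patients, boosting budgets of
300–5000 iterations with ν between 0.1 and 1.0 (ν = 1 only for the
joint-learner MLE route, where each step is a pure fixed-point iteration),
and 5–10 fold CV; these sizes were chosen so each property is measured well
above its Monte-Carlo noise floor. All randomized steps consume explicit
seeds recorded in results.

## Known limitations

- The derivation cohort behind the published coefficients is not publicly
  available; derivation-scale metrics (AUC ≈ 81%, accuracy ≈ 69%) are
  context, not reproduction targets — the pipeline is validated on synthetic
  cohorts instead.
- The random-effect base learner uses a fixed effective-df ridge rather than
  a variance-component estimate; the df is a configuration choice.
- The score is a decision aid for the within-patient question only; absolute
  rupture probabilities additionally require the patient-level terms and are
  only as transportable as the underlying cohort.
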