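# mia-score

Identification of the ruptured aneurysm in subarachnoid hemorrhage (SAH)
patients harboring **multiple intracranial aneurysms (MIAs)**. When the CT
hemorrhage pattern does not point to the bleeding source, the treating team
must still decide which aneurysm to secure first. This package implements, as
a tested pipeline, a clinical prediction score for that decision: its
closed-form published coefficients, the component-wise gradient-boosting
machinery that derives such a score from a cohort, patient-level
cross-validated evaluation, calibration assessment, and a synthetic cohort
generator for validating the whole pipeline without patient data.

## The score

Each aneurysm gets an **aneurysm-specific prediction score**

```
score = A + B + C
A = 0.0427 × size (mm)
B = 0            if location = AcomA / ACA          (reference)
    −0.0104      if location = PcomA
    −0.1831      if location = posterior circulation
    −0.4055      if location = MCA
    −0.5973      if location = ICA (excluding PcomA)
C = 0            if shape = regular                 (reference)
    0.5387       if shape = irregular (lobulated or bleb)
```

Higher scores mean higher rupture risk; **within a patient, the aneurysm with
the maximal score is the predicted bleeding source**. The score is the
aneurysm-specific part of a binomial (logistic-link) model fitted by
component-wise gradient boosting with linear base learners and a
patient-specific random effect; patient-level terms are constant within a
patient and cancel in the argmax, so the three-term score suffices at the
bedside. The score supports, and never replaces, the expert decision.

The underlying statistical model treats each aneurysm as one observation with
binary outcome `ruptured`, additive predictor
`η = β₀ + βᵀx(aneurysm) + γᵀz(patient) + b(patient)` and
`P(rupture) = 1/(1+e^{−η})`; boosting performs data-driven variable selection
and regularizes the coefficients through early stopping, with the stopping
iteration tuned by patient-level ten-fold cross-validation.

## Worked example

The packaged prospective cohort (34 patients, 83 aneurysms, each with size,
five-region location, shape and the validated bleeding source) ships with the
package:

```python
>>> from mia_score import table2_fixture, published_coefficients, rank_patient
>>> cohort = table2_fixture()
>>> patient = cohort.patient("9")   # AcomA 5 mm irregular vs MCA 13 mm regular
>>> pred = rank_patient(patient, published_coefficients())
>>> {a: round(s, 4) for a, s in pred.scores.items()}
{'9-1': 0.7522, '9-2': 0.1496}
>>> pred.predicted
'9-1'
```

The 5 mm irregular AcomA aneurysm (5 × 0.0427 + 0 + 0.5387 = 0.7522) outranks
the much larger 13 mm regular MCA aneurysm (13 × 0.0427 − 0.4055 = 0.1496) —
surgical inspection confirmed the AcomA aneurysm as the bleeding source. Over
the whole cohort:

```
$ mia-score reproduce-table2
recomputed scores matching the printed table: 80/83
  mismatch 2-1: recomputed +0.2458, printed +0.0216 (printed value is a known misprint)
  mismatch 5-7: recomputed -0.0550, printed -0.0556 (printed value is a known misprint)
  mismatch 6-2: recomputed -0.0550, printed -0.0557 (printed value is a known misprint)
ruptured aneurysm attains the maximal score in 33/34 patients
  missed patient 24 (2 aneurysms)
```

(The three mismatching rows are misprints in the source table — two of them
print *different* scores for identical covariates; patient 24 is the one case
where the surgically confirmed source contradicts the score ordering. See
`docs/methods.md`.)

Deriving a score from data, end to end on a synthetic cohort
(`python examples/03_cross_validate.py`):

```
overall accuracy: 74.0% (111/150 patients)
per aneurysm-count stratum (accuracy vs 1/k baseline):
  k=2: 80.8% vs 50.0% (n=104)
  k=3: 67.9% vs 33.3% (n=28)
  k=4: 50.0% vs 25.0% (n=14)
  k=5: 33.3% vs 20.0% (n=3)
  k=6: 0.0% vs 16.7% (n=1)
mean test AUC 76.6%, train 79.5%, complete data 79.4%
```

Accuracy beats random guessing in every populated stratum and declines with
the number of candidate aneurysms; the small train–test AUC gap shows the
early stopping controlling overfitting.

More narrative scripts live in `examples/` (scoring, fitting, CV,
calibration, the 0–40 mm score heatmap). The `mia-score` CLI wires the same
stages for shell use: `simulate`, `impute`, `score`, `rank`, `fit`, `cv`,
`calibrate`, `reproduce-table2`.

## Layout

```
src/mia_score/   cohort.py    domain types, CSV I/O, packaged prospective cohort
                 score.py     closed-form score, ranking, heatmap grid
                 boosting.py  component-wise gradient boosting + score extraction
                 impute.py    single logistic imputation of missing shape
                 evaluate.py  folds, AUC, calibration, nested cross-validation
                 simulate.py  synthetic cohort generator, recovery experiments
                 cli.py       thin command-line wiring
docs/methods.md  model, assumptions, numerical choices, limitations
examples/        one narrative script per capability
tests/           pytest suite (unit, property and acceptance tests)
```
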