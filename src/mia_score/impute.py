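"""Single imputation of missing aneurysm shape.

Shape (regular vs irregular) is the only field allowed to be missing.  Missing
shapes are filled deterministically by one logistic regression of
irregular-vs-regular on all other variables — size, location, the rupture
outcome and the patient covariates — fitted on complete cases; a missing shape
becomes IRREGULAR iff its fitted irregular probability reaches the threshold
(default 0.5).  No stochastic draw, no multiple imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .cohort import Cohort, Location, Patient, Shape

__all__ = ["ImputationReport", "impute_shape"]

_LOC_DUMMIES = [l for l in Location if l is not Location.ACOM_AA]


@dataclass(frozen=True)
class ImputationReport:
    n_missing: int
    n_imputed_regular: int
    n_imputed_irregular: int
    model_coefficients: dict[str, float]
    threshold: float

    def to_dict(self) -> dict:
        return {
            "n_missing": self.n_missing,
            "n_imputed_regular": self.n_imputed_regular,
            "n_imputed_irregular": self.n_imputed_irregular,
            "model_coefficients": self.model_coefficients,
            "threshold": self.threshold,
        }


def _predictor_row(patient: Patient, aneurysm) -> list[float]:
    if aneurysm.ruptured is None:
        raise ValueError(
            f"aneurysm {aneurysm.aneurysm_id}: rupture label missing; only shape may be missing"
        )
    for name, val in (
        ("age_years", patient.age_years),
        ("smoker", patient.smoker),
        ("hypertension", patient.hypertension),
    ):
        if val is None:
            raise ValueError(
                f"patient {patient.patient_id}: {name} missing; only shape may be missing"
            )
    return (
        [aneurysm.size_mm]
        + [1.0 if aneurysm.location is l else 0.0 for l in _LOC_DUMMIES]
        + [
            float(aneurysm.ruptured),
            float(patient.age_years),
            float(patient.smoker),
            float(patient.hypertension),
            float(patient.n_aneurysms),
            float(patient.additional_in_region(aneurysm)),
        ]
    )


_PREDICTOR_NAMES = (
    ["size_mm"]
    + [f"loc_{l.value}" for l in _LOC_DUMMIES]
    + [
        "ruptured",
        "age_years",
        "smoker",
        "hypertension",
        "aneurysms_per_patient",
        "additional_aneurysms_same_region",
    ]
)


def impute_shape(cohort: Cohort, threshold: float = 0.5) -> tuple[Cohort, ImputationReport]:
    """Fill every MISSING shape; returns the completed cohort and a report.

    Non-missing fields are never altered.  Requires complete cases of both
    shape classes; an unpenalized logistic fit is used, so under perfect
    separation the solver stops at its iteration cap with an effectively
    degenerate (but still deterministic) classifier.
    """
    complete_X, complete_y = [], []
    missing: list[tuple[str, list[float]]] = []
    for p, a in cohort.aneurysms():
        if a.shape is Shape.MISSING:
            missing.append((a.aneurysm_id, _predictor_row(p, a)))
        else:
            complete_X.append(_predictor_row(p, a))
            complete_y.append(1.0 if a.shape is Shape.IRREGULAR else 0.0)

    if not missing:
        report = ImputationReport(0, 0, 0, {}, threshold)
        return cohort, report

    y = np.asarray(complete_y)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(
            "degenerate imputation model: complete cases contain only one shape class"
        )
    X = np.asarray(complete_X)
    model = LogisticRegression(C=np.inf, max_iter=2000, tol=1e-8)  # unpenalized
    model.fit(X, y)
    probs = model.predict_proba(np.asarray([row for _, row in missing]))[:, 1]
    assignment = {
        aid: (Shape.IRREGULAR if p >= threshold else Shape.REGULAR)
        for (aid, _), p in zip(missing, probs)
    }

    new_patients = []
    for p in cohort.patients:
        new_patients.append(
            replace(
                p,
                aneurysms=tuple(
                    replace(a, shape=assignment[a.aneurysm_id])
                    if a.aneurysm_id in assignment
                    else a
                    for a in p.aneurysms
                ),
            )
        )
    coefs = dict(zip(_PREDICTOR_NAMES, (float(c) for c in model.coef_[0])))
    coefs["intercept"] = float(model.intercept_[0])
    n_irr = sum(1 for s in assignment.values() if s is Shape.IRREGULAR)
    report = ImputationReport(
        n_missing=len(missing),
        n_imputed_regular=len(missing) - n_irr,
        n_imputed_irregular=n_irr,
        model_coefficients=coefs,
        threshold=threshold,
    )
    return Cohort(tuple(new_patients), provenance=f"{cohort.provenance}|imputed"), report
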