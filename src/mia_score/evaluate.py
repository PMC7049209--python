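"""Patient-level cross-validated evaluation of the rupture score pipeline.

The unit of prediction is the patient: among a patient's k aneurysms the one
with the maximal aneurysm-specific score is the predicted bleeding source, so
fold assignment, accuracy counting and the random-guessing baseline (1/k) all
live on the patient level, while discrimination (AUC) and calibration are
assessed on the aneurysm level from the model's rupture probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .boosting import BoostingConfig, extract_score, fit as boost_fit, predict_prob, select_mstop
from .cohort import Cohort
from .score import rank_patient

__all__ = [
    "EvaluationConfig",
    "FoldResult",
    "EvaluationResult",
    "make_folds",
    "random_guess_baseline",
    "compute_auc",
    "calibration_table",
    "score_accuracy",
    "cross_validate",
]


@dataclass(frozen=True)
class EvaluationConfig:
    outer_folds: int = 10
    seed: int = 0
    boosting: BoostingConfig = field(default_factory=BoostingConfig)
    tie_policy: str = "non_strict"  # non_strict | first | error

    def __post_init__(self):
        if self.outer_folds < 2:
            raise ValueError("outer_folds must be >= 2")
        if self.tie_policy not in {"non_strict", "first", "error"}:
            raise ValueError(f"unknown tie policy {self.tie_policy!r}")


def make_folds(cohort: Cohort, k: int, seed: int) -> dict[int, list[str]]:
    """Mutually exclusive, exhaustive patient-level folds, sizes within 1.

    All of a patient's aneurysms travel with the patient.  Deterministic given
    the seed.
    """
    ids = [p.patient_id for p in cohort.patients]
    if k > len(ids):
        raise ValueError(f"cannot make {k} folds from {len(ids)} patients")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return {
        f: sorted(ids[i] for i in perm[f::k])
        for f in range(k)
    }


def random_guess_baseline(k: int) -> float:
    """Probability of picking the bleeding source among k aneurysms by chance."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 1.0 / k


def compute_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both outcome classes must be present")
    ranks = rankdata(scores)  # average ranks => ties contribute 1/2
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def calibration_table(
    probabilities, outcomes, bin_size: int = 50
) -> pd.DataFrame:
    """Ordered fixed-size calibration bins (remainder appended to the last).

    Fitted probabilities are sorted; ``floor(n / bin_size)`` intervals of
    ``bin_size`` are formed and the leftover observations join the last
    interval.  Returns mean predicted probability, observed rupture frequency
    and count per interval; a ``warning`` flag marks the degenerate
    n < bin_size single-interval case.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    p, y = p[order], y[order]
    warning = n < bin_size
    n_bins = max(1, n // bin_size)
    rows = []
    for b in range(n_bins):
        lo = b * bin_size
        hi = (b + 1) * bin_size if b < n_bins - 1 else n
        rows.append(
            {
                "interval": b + 1,
                "mean_predicted": float(p[lo:hi].mean()),
                "observed_frequency": float(y[lo:hi].mean()),
                "n": hi - lo,
                "warning": warning,
            }
        )
    return pd.DataFrame(rows)


def _patient_hit(patient, coeffs, tie_policy: str) -> bool:
    """Did the within-patient argmax of the score find the bleeding source?"""
    truth = patient.ruptured_aneurysm
    if truth is None:
        raise ValueError(f"patient {patient.patient_id} has no unique rupture label")
    pred = rank_patient(patient, coeffs, tie_policy="error" if tie_policy == "error" else "report")
    if tie_policy == "non_strict":
        return truth.aneurysm_id in pred.argmax_set
    return pred.predicted == truth.aneurysm_id


def score_accuracy(cohort: Cohort, coeffs, tie_policy: str = "non_strict") -> pd.DataFrame:
    """Per-patient argmax correctness of a fixed coefficient set."""
    rows = []
    for p in cohort.patients:
        rows.append(
            {
                "patient_id": p.patient_id,
                "n_aneurysms": p.n_aneurysms,
                "hit": _patient_hit(p, coeffs, tie_policy),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FoldResult:
    fold: int
    n_patients: int
    n_correct: int
    test_auc: float
    train_auc: float
    m_stop: int


@dataclass(frozen=True)
class EvaluationResult:
    per_fold: tuple[FoldResult, ...]
    overall_accuracy: float
    stratified_accuracy: dict[int, float]
    stratum_sizes: dict[int, int]
    baseline: dict[int, float]
    mean_test_auc: float
    mean_train_auc: float
    pooled_test_auc: float
    complete_data_auc: float
    complete_data_mstop: int
    seed: int

    @property
    def n_correct(self) -> int:
        return sum(f.n_correct for f in self.per_fold)

    @property
    def n_patients(self) -> int:
        return sum(f.n_patients for f in self.per_fold)

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "n_correct": self.n_correct,
            "n_patients": self.n_patients,
            "stratified_accuracy": {str(k): v for k, v in self.stratified_accuracy.items()},
            "stratum_sizes": {str(k): v for k, v in self.stratum_sizes.items()},
            "baseline": {str(k): v for k, v in self.baseline.items()},
            "mean_test_auc": self.mean_test_auc,
            "mean_train_auc": self.mean_train_auc,
            "pooled_test_auc": self.pooled_test_auc,
            "complete_data_auc": self.complete_data_auc,
            "complete_data_mstop": self.complete_data_mstop,
            "seed": self.seed,
            "per_fold": [
                {
                    "fold": f.fold,
                    "n_patients": f.n_patients,
                    "n_correct": f.n_correct,
                    "test_auc": f.test_auc,
                    "train_auc": f.train_auc,
                    "m_stop": f.m_stop,
                }
                for f in self.per_fold
            ],
        }


def cross_validate(cohort: Cohort, config: EvaluationConfig) -> EvaluationResult:
    """Nested patient-level cross-validation of the full pipeline.

    For each outer fold the stopping iteration is tuned by inner CV on the
    learning sample only, a model is fitted and its aneurysm-specific score is
    extracted to rank the held-out patients; no held-out aneurysm ever enters
    the learning sample or the inner CV.  AUCs are computed from predicted
    probabilities — without random effects on held-out (unseen) patients, with
    them on the training sample.  A final model on the complete data supplies
    the complete-data AUC (and the fitted probabilities used for calibration).
    """
    folds = make_folds(cohort, config.outer_folds, config.seed)
    per_fold: list[FoldResult] = []
    hits: list[tuple[int, bool]] = []  # (aneurysm count k, correct)
    pooled_scores: list[float] = []
    pooled_labels: list[float] = []
    for f, held_ids in folds.items():
        train = cohort.subset(p.patient_id for p in cohort.patients if p.patient_id not in set(held_ids))
        test = cohort.subset(held_ids)
        boost_cfg = config.boosting
        m_stop, _ = select_mstop(train, boost_cfg)
        fit_ = boost_fit(train, boost_cfg, m_stop)
        coeffs = extract_score(fit_)
        n_correct = 0
        for p in test.patients:
            ok = _patient_hit(p, coeffs, config.tie_policy)
            hits.append((p.n_aneurysms, ok))
            n_correct += ok
        test_pred = predict_prob(fit_, test, use_random_effects=False)
        train_pred = predict_prob(fit_, train, use_random_effects=True)
        pooled_scores.extend(test_pred["probability"])
        pooled_labels.extend(test_pred["ruptured"])
        per_fold.append(
            FoldResult(
                fold=f,
                n_patients=test.n_patients,
                n_correct=n_correct,
                test_auc=compute_auc(test_pred["probability"], test_pred["ruptured"]),
                train_auc=compute_auc(train_pred["probability"], train_pred["ruptured"]),
                m_stop=m_stop,
            )
        )

    strata = sorted({k for k, _ in hits})
    stratified = {
        k: float(np.mean([ok for kk, ok in hits if kk == k])) for k in strata
    }
    sizes = {k: sum(1 for kk, _ in hits if kk == k) for k in strata}
    overall = float(np.mean([ok for _, ok in hits]))

    full_mstop, _ = select_mstop(cohort, config.boosting)
    full_fit = boost_fit(cohort, config.boosting, full_mstop)
    full_pred = predict_prob(full_fit, cohort, use_random_effects=True)
    return EvaluationResult(
        per_fold=tuple(per_fold),
        overall_accuracy=overall,
        stratified_accuracy=stratified,
        stratum_sizes=sizes,
        baseline={k: random_guess_baseline(k) for k in strata},
        mean_test_auc=float(np.mean([f.test_auc for f in per_fold])),
        mean_train_auc=float(np.mean([f.train_auc for f in per_fold])),
        pooled_test_auc=compute_auc(pooled_scores, pooled_labels),
        complete_data_auc=compute_auc(full_pred["probability"], full_pred["ruptured"]),
        complete_data_mstop=full_mstop,
        seed=config.seed,
    )
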