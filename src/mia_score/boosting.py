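"""Component-wise gradient boosting for the binomial rupture model.

The model is an additive logistic regression fitted by functional gradient
descent on the binomial deviance: the additive predictor starts at the
empirical log-odds of rupture, and at every iteration each candidate base
learner is fitted by (penalized) least squares to the negative gradient
``y - p``; only the single best-fitting component is updated, damped by the
step length ``nu``.  Base learners are one simple linear learner per covariate
(slope through the centered covariate) plus, optionally, a ridge-penalized
patient-intercept learner with a fixed effective degrees of freedom that plays
the role of a patient-specific random effect.  Early stopping at ``m_stop``
iterations — tuned by patient-level cross-validation — is the regularizer, and
doubles as data-driven variable selection: a covariate that is never selected
keeps a coefficient of exactly zero.

The aneurysm-specific part of the fit (size, location, shape) is the
prediction score; :func:`extract_score` re-expresses it with the anterior
communicating / anterior cerebral region and regular shape as zero references.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, Location, Shape
from .score import ScoreCoefficients

__all__ = [
    "ANEURYSM_COVARIATES",
    "PATIENT_COVARIATES",
    "DEFAULT_COVARIATES",
    "BoostingConfig",
    "BoostingFit",
    "build_design",
    "fit",
    "select_mstop",
    "predict_prob",
    "extract_score",
]

_LOC_DUMMIES = [l for l in Location if l is not Location.ACOM_AA]

ANEURYSM_COVARIATES = ["size_mm"] + [f"loc_{l.value}" for l in _LOC_DUMMIES] + ["irregular"]
PATIENT_COVARIATES = [
    "age_years",
    "smoker",
    "hypertension",
    "aneurysms_per_patient",
    "additional_aneurysms_same_region",
]
DEFAULT_COVARIATES = ANEURYSM_COVARIATES + PATIENT_COVARIATES

RANDOM_EFFECT = "patient_random_effect"
SCHEMA_VERSION = 1


def build_design(cohort: Cohort) -> pd.DataFrame:
    """One-row-per-aneurysm analysis table.

    Columns: the candidate covariates (location as four dummies with the
    AcomA/AA region as reference, shape as an irregular indicator), the binary
    outcome ``ruptured`` and the ``patient_id`` grouping key.  Derived counts
    (aneurysms per patient, additional aneurysms in the same region) are
    recomputed here, never read from storage.  Patient covariates that were
    never recorded become NaN; downstream fitting refuses NaN among its
    candidates.
    """
    rows = []
    for p in cohort.patients:
        for a in p.aneurysms:
            if a.shape is Shape.MISSING:
                raise ValueError(
                    f"aneurysm {a.aneurysm_id}: shape is missing; impute before building the design"
                )
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "aneurysm_id": a.aneurysm_id,
                    "ruptured": np.nan if a.ruptured is None else float(a.ruptured),
                    "size_mm": float(a.size_mm),
                    **{f"loc_{l.value}": float(a.location is l) for l in _LOC_DUMMIES},
                    "irregular": float(a.shape is Shape.IRREGULAR),
                    "age_years": np.nan if p.age_years is None else float(p.age_years),
                    "smoker": np.nan if p.smoker is None else float(p.smoker),
                    "hypertension": np.nan if p.hypertension is None else float(p.hypertension),
                    "aneurysms_per_patient": float(p.n_aneurysms),
                    "additional_aneurysms_same_region": float(p.additional_in_region(a)),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BoostingConfig:
    """Tuning knobs of the boosting run.

    ``step_length_nu`` is the damping factor applied to every selected base
    learner; ``random_effect_df`` the effective degrees of freedom of the
    ridge-penalized patient-intercept learner (the ridge penalty is solved
    from it); ``single_learner=True`` replaces component-wise selection by one
    joint multivariable least-squares learner over all candidates, which turns
    the algorithm into plain functional gradient descent toward the logistic
    maximum-likelihood fit (no variable selection).
    """

    step_length_nu: float = 0.1
    max_iterations: int = 1000
    inner_cv_folds: int = 10
    random_effect_df: float = 4.0
    seed: int = 0
    candidate_covariates: tuple[str, ...] = tuple(DEFAULT_COVARIATES)
    use_random_effect: bool = True
    single_learner: bool = False

    def __post_init__(self):
        if not 0 < self.step_length_nu <= 1:
            raise ValueError("step_length_nu must be in (0, 1]")
        if self.max_iterations < 1 or self.inner_cv_folds < 2:
            raise ValueError("max_iterations >= 1 and inner_cv_folds >= 2 required")


@dataclass
class BoostingFit:
    """Accumulated fit on the raw covariate scale.

    ``intercept`` already absorbs the log-odds offset and the centering
    constants, so the additive predictor of an aneurysm is
    ``intercept + sum(coefficients[j] * x_j) (+ random_intercepts[patient])``.
    Unselected covariates keep coefficient exactly 0.
    """

    intercept: float
    coefficients: dict[str, float]
    random_intercepts: dict[str, float]
    m_stop: int
    step_length_nu: float
    selection_path: list[str]
    deviance_path: list[float]
    centering: dict[str, float]
    schema_version: int = SCHEMA_VERSION

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "schema_version": self.schema_version,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "random_intercepts": self.random_intercepts,
            "m_stop": self.m_stop,
            "step_length_nu": self.step_length_nu,
            "selection_path": self.selection_path,
            "deviance_path": self.deviance_path,
            "centering": self.centering,
        }
        s = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "BoostingFit":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
        if doc.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported fit schema version {doc.get('schema_version')}")
        return cls(**{k: v for k, v in doc.items()})


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _ridge_lambda(group_sizes: np.ndarray, df: float) -> float:
    """Ridge penalty such that the grouped-intercept learner has the given
    effective degrees of freedom, sum n_g / (n_g + lambda) = df."""
    if df >= len(group_sizes):
        return 0.0
    lo, hi = 0.0, 1.0
    while np.sum(group_sizes / (group_sizes + hi)) > df:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.sum(group_sizes / (group_sizes + mid)) > df:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class _BoostState:
    """Vectorized inner loop shared by fit() and the CV deviance curves."""

    def __init__(self, design: pd.DataFrame, config: BoostingConfig):
        y = design["ruptured"].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError("unlabelled aneurysms in the training design")
        if y.sum() == 0 or y.sum() == len(y):
            raise ValueError("degenerate outcome: all aneurysms share one rupture label")
        self.y = y
        self.names = list(config.candidate_covariates)
        X = design[self.names].to_numpy(dtype=float)
        if np.isnan(X).any():
            bad = [n for n in self.names if design[n].isna().any()]
            raise ValueError(f"NaN in candidate covariates {bad}; only shape may be missing")
        self.means = X.mean(axis=0)
        self.Xc = X - self.means
        self.sxx = np.einsum("ij,ij->j", self.Xc, self.Xc)
        self.config = config

        codes, uniques = pd.factorize(design["patient_id"])
        self.group_codes = codes
        self.group_ids = list(uniques)
        self.group_sizes = np.bincount(codes).astype(float)
        self.re_lambda = _ridge_lambda(self.group_sizes, config.random_effect_df)

        base_rate = y.mean()
        self.offset = float(np.log(base_rate / (1 - base_rate)))
        self.eta = np.full(len(y), self.offset)
        self.coef = np.zeros(len(self.names))
        self.re = np.zeros(len(self.group_sizes))
        self.selection_path: list[str] = []
        self.deviance_path: list[float] = []
        self.intercept_adj = 0.0
        if config.single_learner:
            # Precompute the pseudoinverse once; the joint learner refits all
            # covariates plus a free intercept at every iteration (no
            # selection), so its fixed point is the logistic ML solution.
            self.pinv = np.linalg.pinv(np.column_stack([np.ones(len(y)), self.Xc]))

    def best_component(self, u: np.ndarray) -> tuple[int | str, object]:
        """Brute-force least-squares fit of every base learner to the
        working residual u; returns the component with minimal RSS."""
        uu = float(u @ u)
        with np.errstate(divide="ignore", invalid="ignore"):
            slopes = np.where(self.sxx > 0, (self.Xc.T @ u) / np.where(self.sxx > 0, self.sxx, 1.0), 0.0)
        rss = uu - slopes**2 * self.sxx
        best_j = int(np.argmin(rss))
        best_rss = rss[best_j]
        if self.config.use_random_effect:
            gsum = np.bincount(self.group_codes, weights=u, minlength=len(self.group_sizes))
            c = gsum / (self.group_sizes + self.re_lambda)
            rss_re = uu - 2 * float(c @ gsum) + float(c**2 @ self.group_sizes)
            if rss_re < best_rss:
                return RANDOM_EFFECT, c
        return best_j, float(slopes[best_j])

    def step(self) -> None:
        nu = self.config.step_length_nu
        p = 1.0 / (1.0 + np.exp(-self.eta))
        u = self.y - p
        if self.config.single_learner:
            beta = self.pinv @ u
            self.intercept_adj += nu * beta[0]
            self.coef += nu * beta[1:]
            self.eta += nu * (beta[0] + self.Xc @ beta[1:])
            self.selection_path.append("all")
        else:
            which, fitted = self.best_component(u)
            if which == RANDOM_EFFECT:
                self.re += nu * fitted
                self.eta += nu * fitted[self.group_codes]
                self.selection_path.append(RANDOM_EFFECT)
            else:
                self.coef[which] += nu * fitted
                self.eta += nu * fitted * self.Xc[:, which]
                self.selection_path.append(self.names[which])
        self.deviance_path.append(_deviance(self.y, 1.0 / (1.0 + np.exp(-self.eta))))

    def as_fit(self) -> BoostingFit:
        intercept = self.offset + self.intercept_adj - float(self.coef @ self.means)
        return BoostingFit(
            intercept=intercept,
            coefficients={n: float(c) for n, c in zip(self.names, self.coef)},
            random_intercepts={
                g: float(r) for g, r in zip(self.group_ids, self.re) if r != 0.0
            },
            m_stop=len(self.selection_path),
            step_length_nu=self.config.step_length_nu,
            selection_path=list(self.selection_path),
            deviance_path=list(self.deviance_path),
            centering={n: float(m) for n, m in zip(self.names, self.means)},
        )


def fit(cohort: Cohort, config: BoostingConfig, m_stop: int) -> BoostingFit:
    """Run ``m_stop`` boosting iterations on the cohort's design table."""
    if m_stop > config.max_iterations:
        raise ValueError("m_stop exceeds config.max_iterations")
    return fit_design(build_design(cohort), config, m_stop)


def fit_design(design: pd.DataFrame, config: BoostingConfig, m_stop: int) -> BoostingFit:
    state = _BoostState(design, config)
    for _ in range(m_stop):
        state.step()
    return state.as_fit()


def _eta_on(design: pd.DataFrame, fit_: BoostingFit, use_random_effects: bool) -> np.ndarray:
    X = design[list(fit_.coefficients)].to_numpy(dtype=float)
    coef = np.array(list(fit_.coefficients.values()))
    active = coef != 0
    if np.isnan(X[:, active]).any():
        bad = [n for n, a in zip(fit_.coefficients, active) if a and design[n].isna().any()]
        raise ValueError(f"NaN in covariates with nonzero coefficients: {bad}")
    eta = fit_.intercept + np.where(np.isnan(X), 0.0, X) @ coef
    if use_random_effects:
        eta = eta + design["patient_id"].map(fit_.random_intercepts).fillna(0.0).to_numpy()
    return eta


def predict_prob(
    fit_: BoostingFit, cohort: Cohort, use_random_effects: bool = False
) -> pd.DataFrame:
    """Per-aneurysm rupture probability under the fitted model.

    Patients unseen during training get a zero random intercept.
    """
    design = build_design(cohort)
    eta = _eta_on(design, fit_, use_random_effects)
    out = design[["patient_id", "aneurysm_id", "ruptured"]].copy()
    out["eta"] = eta
    out["probability"] = 1.0 / (1.0 + np.exp(-eta))
    return out


def select_mstop(
    cohort: Cohort, config: BoostingConfig
) -> tuple[int, np.ndarray]:
    """Tune the stopping iteration by patient-level cross-validation.

    Patients are split into ``inner_cv_folds`` folds (deterministic given
    ``config.seed``); for each fold a full boosting path is grown on the
    remaining patients and the held-out binomial deviance is accumulated at
    every iteration.  Returns the iteration with minimal mean held-out
    deviance and the full summed-deviance curve (index m-1 <-> m iterations).
    """
    from .evaluate import make_folds  # local import to avoid a cycle

    folds = make_folds(cohort, config.inner_cv_folds, config.seed)
    design = build_design(cohort)
    curve = np.zeros(config.max_iterations)
    for fold_patients in folds.values():
        held = design["patient_id"].isin(fold_patients).to_numpy()
        state = _BoostState(design[~held].reset_index(drop=True), config)
        vy = design.loc[held, "ruptured"].to_numpy(dtype=float)
        Xv = design.loc[held, list(state.names)].to_numpy(dtype=float) - state.means
        veta = np.full(held.sum(), state.offset)
        prev_coef = state.coef.copy()
        for m in range(config.max_iterations):
            state.step()
            # held-out patients are unseen, so random-effect steps leave their
            # predictor unchanged; covariate steps update it incrementally.
            delta = state.coef - prev_coef
            if np.any(delta):
                veta = veta + Xv @ delta
            prev_coef = state.coef.copy()
            curve[m] += _deviance(vy, 1.0 / (1.0 + np.exp(-veta)))
    best = int(np.argmin(curve)) + 1
    return best, curve


def extract_score(fit_: BoostingFit) -> ScoreCoefficients:
    """The aneurysm-specific linear part of a fit as closed-form coefficients.

    Location dummies already measure offsets against the AcomA/AA reference
    and the shape dummy against regular shape, so on the raw covariate scale
    the extraction is exact; intercept, centering constants and patient-level
    terms shift all of a patient's scores equally and drop out of the
    within-patient ranking.
    """
    c = fit_.coefficients
    return ScoreCoefficients(
        size_slope=c.get("size_mm", 0.0),
        location_offset={
            Location.ACOM_AA: 0.0,
            **{l: c.get(f"loc_{l.value}", 0.0) for l in _LOC_DUMMIES},
        },
        irregular_offset=c.get("irregular", 0.0),
    )
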