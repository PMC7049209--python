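"""The aneurysm-specific rupture prediction score and within-patient ranking.

The score is a linear combination of three aneurysm-level characteristics,

    score = slope * size_mm + location_offset[region] + shape_offset,

with the anterior communicating / anterior cerebral region and regular shape
as zero reference levels.  Higher scores mean higher rupture risk.  The score
is only defined up to within-patient comparison: patient-level terms of the
underlying logistic model are constant within a patient and cancel in the
argmax, so the aneurysm with the maximal score is the predicted bleeding
source.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, Location, Patient, Shape

__all__ = [
    "ScoreCoefficients",
    "PatientPrediction",
    "published_coefficients",
    "compute_score",
    "round_score",
    "rank_patient",
    "rank_cohort",
    "score_frame",
    "heatmap_grid",
]


def round_score(x: float, ndigits: int = 4) -> float:
    """Round half away from zero, the convention of the printed score tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ScoreCoefficients:
    """Closed-form score: size slope, five location offsets, shape offset.

    ``location_offset[ACOM_AA]`` and ``regular_offset`` are fixed zero
    reference levels.
    """

    size_slope: float
    location_offset: dict[Location, float]
    irregular_offset: float
    regular_offset: float = 0.0

    def __post_init__(self):
        missing = [l for l in Location if l not in self.location_offset]
        if missing:
            raise ValueError(f"location_offset missing regions: {missing}")
        if self.location_offset[Location.ACOM_AA] != 0.0:
            raise ValueError("ACOM_AA is the reference region; its offset must be 0")
        if self.regular_offset != 0.0:
            raise ValueError("regular shape is the reference level; its offset must be 0")

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "size_slope": self.size_slope,
            "location_offset": {l.value: v for l, v in self.location_offset.items()},
            "irregular_offset": self.irregular_offset,
            "regular_offset": self.regular_offset,
        }
        s = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "ScoreCoefficients":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
        return cls(
            size_slope=doc["size_slope"],
            location_offset={Location(k): v for k, v in doc["location_offset"].items()},
            irregular_offset=doc["irregular_offset"],
            regular_offset=doc.get("regular_offset", 0.0),
        )


def published_coefficients() -> ScoreCoefficients:
    """The coefficients of the published closed-form score."""
    return ScoreCoefficients(
        size_slope=0.0427,
        location_offset={
            Location.ACOM_AA: 0.0,
            Location.PCOM: -0.0104,
            Location.POSTERIOR: -0.1831,
            Location.MCA: -0.4055,
            Location.ICA_WO_PCOM: -0.5973,
        },
        irregular_offset=0.5387,
    )


def compute_score(
    size_mm: float,
    location: Location,
    shape: Shape,
    coeffs: ScoreCoefficients | None = None,
) -> float:
    """Unrounded score for one aneurysm; unbounded in both directions.

    ``shape`` must not be MISSING — impute first (see :mod:`mia_score.impute`).
    """
    if coeffs is None:
        coeffs = published_coefficients()
    if shape is Shape.MISSING:
        raise ValueError("shape is missing: run shape imputation before scoring")
    if not size_mm >= 0:
        raise ValueError(f"size_mm must be positive, got {size_mm}")
    shape_offset = coeffs.irregular_offset if shape is Shape.IRREGULAR else coeffs.regular_offset
    return size_mm * coeffs.size_slope + coeffs.location_offset[Location(location)] + shape_offset


@dataclass(frozen=True)
class PatientPrediction:
    patient_id: str
    scores: dict[str, float]          # aneurysm_id -> unrounded score
    argmax_set: frozenset[str]        # ids attaining the exact maximum
    predicted: str                    # tie-policy-resolved single id
    tie: bool


def rank_patient(
    patient: Patient,
    coeffs: ScoreCoefficients | None = None,
    tie_policy: str = "report",
) -> PatientPrediction:
    """Score every aneurysm of one patient and take the within-patient argmax.

    Ties are detected by exact equality of the unrounded scores.  Policies:
    ``report`` (default) keeps the whole argmax set, flags the tie and resolves
    ``predicted`` to the first argmax member in table order; ``first`` is the
    same resolution without the multi-member set semantics downstream;
    ``error`` raises on a tie.
    """
    if patient.n_aneurysms == 0:
        raise ValueError(f"patient {patient.patient_id} has no aneurysms")
    if tie_policy not in {"report", "first", "error"}:
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    scores = {a.aneurysm_id: compute_score(a.size_mm, a.location, a.shape, coeffs)
              for a in patient.aneurysms}
    best = max(scores.values())
    argmax = [a.aneurysm_id for a in patient.aneurysms if scores[a.aneurysm_id] == best]
    tie = len(argmax) > 1
    if tie and tie_policy == "error":
        raise ValueError(f"patient {patient.patient_id}: exact score tie among {argmax}")
    return PatientPrediction(
        patient_id=patient.patient_id,
        scores=scores,
        argmax_set=frozenset(argmax),
        predicted=argmax[0],
        tie=tie,
    )


def rank_cohort(
    cohort: Cohort,
    coeffs: ScoreCoefficients | None = None,
    tie_policy: str = "report",
) -> list[PatientPrediction]:
    return [rank_patient(p, coeffs, tie_policy) for p in cohort.patients]


def score_frame(cohort: Cohort, coeffs: ScoreCoefficients | None = None) -> pd.DataFrame:
    """Cohort table augmented with score, within-patient rank and argmax flags."""
    rows = []
    for patient in cohort.patients:
        pred = rank_patient(patient, coeffs)
        ordered = sorted(pred.scores.values(), reverse=True)
        for a in patient.aneurysms:
            s = pred.scores[a.aneurysm_id]
            rows.append(
                {
                    "patient_id": patient.patient_id,
                    "aneurysm_id": a.aneurysm_id,
                    "size_mm": a.size_mm,
                    "location": a.location.value,
                    "shape": a.shape.value,
                    "score": s,
                    "score_rounded": round_score(s),
                    "rank_in_patient": ordered.index(s) + 1,
                    "is_argmax": a.aneurysm_id in pred.argmax_set,
                    "tie": pred.tie,
                }
            )
    return pd.DataFrame(rows)


def heatmap_grid(
    coeffs: ScoreCoefficients | None = None,
    size_min: float = 0.0,
    size_max: float = 40.0,
    step: float = 1.0,
) -> pd.DataFrame:
    """Dense long-format score grid over size x location x shape.

    The default 0-40 mm range spans the sizes at which the score is displayed
    as a risk heatmap; every (location, shape) row of the grid is strictly
    increasing in size because the size slope is positive.
    """
    if not step > 0:
        raise ValueError("step must be positive")
    if not size_min < size_max:
        raise ValueError("size_min must be smaller than size_max")
    if coeffs is None:
        coeffs = published_coefficients()
    sizes = np.arange(size_min, size_max + step / 2, step)
    rows = [
        {
            "size_mm": float(s),
            "location": loc.value,
            "shape": shape.value,
            "score": compute_score(float(s), loc, shape, coeffs),
        }
        for loc in Location
        for shape in (Shape.REGULAR, Shape.IRREGULAR)
        for s in sizes
    ]
    return pd.DataFrame(rows)


def plot_heatmap(grid: pd.DataFrame, path: str | Path) -> None:
    """Render the score grid as a heatmap image (one band per location x shape)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = grid.pivot_table(
        index=["location", "shape"], columns="size_mm", values="score", sort=False
    )
    fig, ax = plt.subplots(figsize=(9, 4))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="RdYlBu_r")
    ax.set_yticks(range(len(pivot.index)), [f"{l} / {s}" for l, s in pivot.index])
    cols = pivot.columns.to_list()
    tick = max(1, len(cols) // 8)
    ax.set_xticks(range(0, len(cols), tick), [f"{c:g}" for c in cols[::tick]])
    ax.set_xlabel("aneurysm size (mm)")
    fig.colorbar(im, ax=ax, label="prediction score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
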