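"""Domain types for multiple-intracranial-aneurysm (MIA) cohorts.

One row of a cohort table is a single aneurysm; a patient with subarachnoid
hemorrhage (SAH) contributes one row per aneurysm, and in a rupture-labelled
cohort exactly one of those rows is the bleeding source.  Aneurysm location is
pooled into five vascular regions, aneurysm shape is dichotomized into
regular vs irregular (multilobulated or bleb-bearing), and size is the maximum
diameter in millimetres.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "Location",
    "Shape",
    "Aneurysm",
    "Patient",
    "Cohort",
    "Violation",
    "ValidationReport",
    "SchemaError",
    "IntegrityError",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "table2_fixture",
    "SITE_TO_REGION",
]

MAX_SIZE_MM = 100.0

CSV_COLUMNS = [
    "patient_id",
    "aneurysm_id",
    "size_mm",
    "location",
    "shape",
    "ruptured",
    "age_years",
    "smoker",
    "hypertension",
]


class Location(str, enum.Enum):
    """Five-region location vocabulary for intracranial aneurysms."""

    ACOM_AA = "ACOM_AA"          # anterior communicating / anterior cerebral artery
    PCOM = "PCOM"                # posterior communicating artery
    POSTERIOR = "POSTERIOR"      # posterior circulation (basilar, VA, PICA, SCA, P1, ...)
    MCA = "MCA"                  # middle cerebral artery
    ICA_WO_PCOM = "ICA_WO_PCOM"  # internal carotid artery excluding PcomA segment


class Shape(str, enum.Enum):
    REGULAR = "regular"
    IRREGULAR = "irregular"
    MISSING = "NA"


#: Fine-grained angiographic sites pooled into the five regions.  The pooling
#: follows the region definitions of the score (AcomA with the ACA segments;
#: ophthalmic counted with the ICA; everything vertebrobasilar as posterior).
SITE_TO_REGION: dict[str, Location] = {
    "AcomA": Location.ACOM_AA,
    "ACA": Location.ACOM_AA,
    "A1": Location.ACOM_AA,
    "A2": Location.ACOM_AA,
    "A3": Location.ACOM_AA,
    "PcomA": Location.PCOM,
    "Basilar tip": Location.POSTERIOR,
    "Basilar side": Location.POSTERIOR,
    "P1": Location.POSTERIOR,
    "PICA": Location.POSTERIOR,
    "SCA": Location.POSTERIOR,
    "VA": Location.POSTERIOR,
    "VB junction": Location.POSTERIOR,
    "MCA": Location.MCA,
    "M2": Location.MCA,
    "M3": Location.MCA,
    "ICA": Location.ICA_WO_PCOM,
    "OphthalmicA": Location.ICA_WO_PCOM,
}


class SchemaError(ValueError):
    """The input table does not follow the documented CSV schema."""


class IntegrityError(ValueError):
    """Duplicate identifiers or other referential problems in a cohort file."""


@dataclass(frozen=True)
class Aneurysm:
    """A single candidate lesion tied to a patient.

    ``ruptured`` is ternary: True / False / None (unlabelled cohort).
    """

    aneurysm_id: str
    patient_id: str
    size_mm: float
    location: Location
    shape: Shape
    ruptured: bool | None = None


@dataclass(frozen=True)
class Patient:
    patient_id: str
    aneurysms: tuple[Aneurysm, ...]
    age_years: float | None = None
    smoker: bool | None = None
    hypertension: bool | None = None

    @property
    def n_aneurysms(self) -> int:
        return len(self.aneurysms)

    @property
    def ruptured_aneurysm(self) -> Aneurysm | None:
        """The labelled bleeding source, if the patient carries exactly one."""
        hits = [a for a in self.aneurysms if a.ruptured is True]
        return hits[0] if len(hits) == 1 else None

    def additional_in_region(self, aneurysm: Aneurysm) -> int:
        """Number of the patient's *other* aneurysms in the same region."""
        return sum(
            1
            for a in self.aneurysms
            if a.aneurysm_id != aneurysm.aneurysm_id and a.location == aneurysm.location
        )


@dataclass(frozen=True)
class Cohort:
    patients: tuple[Patient, ...]
    provenance: str = ""

    def __iter__(self) -> Iterator[Patient]:
        return iter(self.patients)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_aneurysms(self) -> int:
        return sum(p.n_aneurysms for p in self.patients)

    def aneurysms(self) -> Iterator[tuple[Patient, Aneurysm]]:
        for p in self.patients:
            for a in p.aneurysms:
                yield p, a

    def patient(self, patient_id: str) -> Patient:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def subset(self, patient_ids: Iterable[str]) -> "Cohort":
        wanted = set(patient_ids)
        kept = tuple(p for p in self.patients if p.patient_id in wanted)
        missing = wanted - {p.patient_id for p in kept}
        if missing:
            raise KeyError(f"unknown patient ids: {sorted(missing)}")
        return Cohort(patients=kept, provenance=f"{self.provenance}|subset")


@dataclass(frozen=True)
class Violation:
    kind: str
    subject: str  # patient_id or aneurysm_id
    message: str


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[Violation, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)


def validate_cohort(cohort: Cohort, require_multiple: bool = False) -> ValidationReport:
    """Check every cohort invariant; never raises, only reports.

    With ``require_multiple`` the cohort is additionally held to the
    multiple-aneurysm contract (>= 2 aneurysms per patient).
    """
    out: list[Violation] = []
    seen_patients: set[str] = set()
    seen_aneurysms: set[str] = set()
    for p in cohort.patients:
        if p.patient_id in seen_patients:
            out.append(Violation("duplicate_patient_id", p.patient_id, "patient_id occurs twice"))
        seen_patients.add(p.patient_id)
        if p.n_aneurysms < 1:
            out.append(Violation("no_aneurysms", p.patient_id, "patient has no aneurysms"))
        if require_multiple and p.n_aneurysms < 2:
            out.append(
                Violation("single_aneurysm", p.patient_id, "multiple-aneurysm cohort requires >= 2")
            )
        labels = [a.ruptured for a in p.aneurysms]
        if any(l is not None for l in labels):
            n_ruptured = sum(1 for l in labels if l is True)
            if n_ruptured != 1:
                out.append(
                    Violation(
                        "rupture_count",
                        p.patient_id,
                        f"labelled patient has {n_ruptured} ruptured aneurysms (exactly 1 expected)",
                    )
                )
        if p.age_years is not None and not p.age_years > 0:
            out.append(Violation("age_nonpositive", p.patient_id, f"age_years = {p.age_years}"))
        for a in p.aneurysms:
            if a.aneurysm_id in seen_aneurysms:
                out.append(Violation("duplicate_aneurysm_id", a.aneurysm_id, "aneurysm_id occurs twice"))
            seen_aneurysms.add(a.aneurysm_id)
            if a.patient_id != p.patient_id:
                out.append(Violation("patient_mismatch", a.aneurysm_id, "aneurysm held by wrong patient"))
            if not (a.size_mm > 0 and a.size_mm <= MAX_SIZE_MM):
                out.append(
                    Violation("size_out_of_range", a.aneurysm_id, f"size_mm = {a.size_mm} not in (0, {MAX_SIZE_MM}]")
                )
    return ValidationReport(tuple(out))


# ---------------------------------------------------------------------------
# CSV interchange


def _parse_bool(raw: str, column: str, row: int) -> bool | None:
    s = str(raw).strip()
    if s in {"", "NA", "nan"}:
        return None
    if s in {"1", "1.0", "True", "true"}:
        return True
    if s in {"0", "0.0", "False", "false"}:
        return False
    raise SchemaError(f"row {row}: column {column!r} has unparseable value {raw!r}")


def read_cohort(path: str | Path, strict: bool = True) -> Cohort | tuple[Cohort, ValidationReport]:
    """Read a one-row-per-aneurysm cohort CSV.

    Schema: ``patient_id, aneurysm_id, size_mm, location, shape, ruptured,
    age_years, smoker, hypertension`` (extra columns are carried along but
    ignored).  ``ruptured`` and the patient covariates may be NA.

    With ``strict=True`` (default) any invariant violation raises; with
    ``strict=False`` returns ``(cohort, report)``.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, comment="#", keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")

    patients: dict[str, dict] = {}
    order: list[str] = []
    seen_aneurysms: set[str] = set()
    for i, rec in enumerate(df.to_dict("records")):
        row = i + 2  # header is line 1
        pid = str(rec["patient_id"]).strip()
        aid = str(rec["aneurysm_id"]).strip()
        if aid in seen_aneurysms:
            raise IntegrityError(f"row {row}: duplicate aneurysm_id {aid!r}")
        seen_aneurysms.add(aid)
        try:
            size = float(rec["size_mm"])
        except ValueError as exc:
            raise SchemaError(f"row {row}: size_mm {rec['size_mm']!r} is not a number") from exc
        loc_raw = str(rec["location"]).strip()
        try:
            loc = Location(loc_raw)
        except ValueError as exc:
            raise ValueError(
                f"row {row}: unknown location label {loc_raw!r}; "
                f"expected one of {[l.value for l in Location]}"
            ) from exc
        shape_raw = str(rec["shape"]).strip()
        try:
            shape = Shape(shape_raw if shape_raw else "NA")
        except ValueError as exc:
            raise ValueError(f"row {row}: unknown shape label {shape_raw!r}") from exc
        ruptured = _parse_bool(rec["ruptured"], "ruptured", row)
        age_raw = str(rec["age_years"]).strip()
        age = None if age_raw in {"", "NA", "nan"} else float(age_raw)
        smoker = _parse_bool(rec["smoker"], "smoker", row)
        aht = _parse_bool(rec["hypertension"], "hypertension", row)

        if pid not in patients:
            patients[pid] = {"age": age, "smoker": smoker, "aht": aht, "aneurysms": []}
            order.append(pid)
        patients[pid]["aneurysms"].append(
            Aneurysm(aneurysm_id=aid, patient_id=pid, size_mm=size, location=loc,
                     shape=shape, ruptured=ruptured)
        )

    cohort = Cohort(
        patients=tuple(
            Patient(
                patient_id=pid,
                aneurysms=tuple(patients[pid]["aneurysms"]),
                age_years=patients[pid]["age"],
                smoker=patients[pid]["smoker"],
                hypertension=patients[pid]["aht"],
            )
            for pid in order
        ),
        provenance=str(path),
    )
    report = validate_cohort(cohort)
    if strict:
        if not report.ok:
            v = report.violations[0]
            raise IntegrityError(f"{path.name}: {len(report)} violation(s); first: {v.kind} on {v.subject}: {v.message}")
        return cohort
    return cohort, report


def _bool_cell(v: bool | None) -> str:
    return "NA" if v is None else str(int(v))


def cohort_frame(cohort: Cohort) -> pd.DataFrame:
    """The cohort as its canonical one-row-per-aneurysm table."""
    rows = []
    for p, a in cohort.aneurysms():
        rows.append(
            {
                "patient_id": p.patient_id,
                "aneurysm_id": a.aneurysm_id,
                "size_mm": a.size_mm,
                "location": a.location.value,
                "shape": a.shape.value,
                "ruptured": _bool_cell(a.ruptured),
                "age_years": "NA" if p.age_years is None else p.age_years,
                "smoker": _bool_cell(p.smoker),
                "hypertension": _bool_cell(p.hypertension),
            }
        )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_cohort(cohort: Cohort, path: str | Path, header_comment: str | None = None) -> None:
    """Write the canonical CSV; ``header_comment`` becomes a leading ``#`` line."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        cohort_frame(cohort).to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Packaged prospective cohort (34 patients / 83 aneurysms)

_FIXTURE_PATH = Path(__file__).parent / "data" / "table2_prospective.csv"


def table2_fixture(with_reference: bool = False):
    """The packaged 34-patient prospective validation cohort.

    Each aneurysm carries size, five-region location, shape, and the
    rupture label established by surgical inspection where available and by
    expert/bleeding-pattern validation otherwise.  The packaged file carries
    two auxiliary reference columns that are *not* part of the cohort proper:
    ``published_score`` (the score as printed in the source table, used only
    to cross-check the scoring arithmetic — three rows are known misprints)
    and ``site`` (the fine-grained angiographic site before pooling).

    With ``with_reference=True`` returns ``(cohort, reference_frame)``.
    """
    cohort = read_cohort(_FIXTURE_PATH, strict=True)
    cohort = replace(cohort, provenance="table2_prospective")
    if not with_reference:
        return cohort
    ref = pd.read_csv(_FIXTURE_PATH, comment="#")
    return cohort, ref
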