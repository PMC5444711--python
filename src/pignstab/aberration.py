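"""Expression/protein aberration classification of patient cohorts.

The aberrant expression pattern of interest is *increased transcriptional
activity with diminished-to-no protein production*: transcript fold
change (relative qPCR quantification) is elevated while the protein is
undetectable on western blot. The packaged patient table ships protein
status, transcript fold expression, karyotype and TP53-deletion status
for a 48-patient MDS / AML-MRC cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

NOT_DETERMINED = "not_determined"
DEFAULT_FOLD_THRESHOLD = 2.0


@dataclass(frozen=True)
class QPCRMeasurement:
    """Ct values for target and reference gene in a sample and calibrator."""

    sample_id: str
    ct_target: float
    ct_reference: float
    calibrator_ct_target: float
    calibrator_ct_reference: float

    def __post_init__(self) -> None:
        for name in (
            "ct_target",
            "ct_reference",
            "calibrator_ct_target",
            "calibrator_ct_reference",
        ):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")


def fold_change(m: QPCRMeasurement) -> float:
    """Relative expression by the delta-delta-Ct method (100% efficiency).

    fold = 2 ** -[(Ct_target - Ct_ref)_sample - (Ct_target - Ct_ref)_calibrator]
    """
    ddct = (m.ct_target - m.ct_reference) - (
        m.calibrator_ct_target - m.calibrator_ct_reference
    )
    return 2.0 ** (-ddct)


@dataclass(frozen=True)
class PatientRecord:
    id: str
    age: int | None = None
    sex: str = ""
    tp53_deletion: str = "-"  # '+' or '-'
    protein_status: str = NOT_DETERMINED  # 'present', 'absent', not_determined
    fold_expression: float | None = None  # None = not determined
    karyotype: str = ""  # 'Normal' or 'Complex'

    def __post_init__(self) -> None:
        if self.protein_status not in ("present", "absent", NOT_DETERMINED):
            raise ValueError(f"bad protein_status {self.protein_status!r}")
        if self.fold_expression is not None and self.fold_expression < 0:
            raise ValueError("fold_expression must be >= 0 when determined")


@dataclass(frozen=True)
class AberrationCall:
    call: str  # 'aberrant', 'concordant', 'indeterminate'
    basis: str


def classify_sample(
    p: PatientRecord,
    fold_up_threshold: float = DEFAULT_FOLD_THRESHOLD,
    strict: bool = False,
) -> AberrationCall:
    """Classify one patient as aberrant / concordant / indeterminate.

    The default rule keys on protein absence — the pattern's defining,
    consistently scored component — and records in ``basis`` whether the
    transcript fold also clears ``fold_up_threshold``. ``strict=True``
    additionally requires the elevated fold, matching the verbal
    definition literally (which excludes absent-protein patients whose
    fold is below threshold).
    """
    if p.protein_status == NOT_DETERMINED or p.fold_expression is None:
        missing = []
        if p.protein_status == NOT_DETERMINED:
            missing.append("protein status")
        if p.fold_expression is None:
            missing.append("fold expression")
        return AberrationCall("indeterminate", f"{' and '.join(missing)} not determined")
    fold_up = p.fold_expression >= fold_up_threshold
    if p.protein_status == "present":
        return AberrationCall(
            "concordant", f"protein present (fold {p.fold_expression:g})"
        )
    # protein absent
    basis = (
        f"protein absent, fold {p.fold_expression:g} "
        f"{'>=':s} {fold_up_threshold:g}" if fold_up
        else f"protein absent, fold {p.fold_expression:g} < {fold_up_threshold:g}"
    )
    if strict and not fold_up:
        return AberrationCall("concordant", basis + " (strict mode)")
    return AberrationCall("aberrant", basis)


def cohort_summary(
    records: list[PatientRecord],
    fold_up_threshold: float = DEFAULT_FOLD_THRESHOLD,
    strict: bool = False,
) -> dict[str, int]:
    """Cohort counts: total, protein-determined, aberrant, and covariates."""
    if not records:
        raise ValueError("no patient records")
    determined = [r for r in records if r.protein_status != NOT_DETERMINED]
    aberrant = sum(
        1
        for r in records
        if classify_sample(r, fold_up_threshold, strict).call == "aberrant"
    )
    return {
        "total": len(records),
        "determined": len(determined),
        "aberrant": aberrant,
        "protein_absent": sum(1 for r in determined if r.protein_status == "absent"),
        "complex_karyotype": sum(1 for r in records if r.karyotype == "Complex"),
        "tp53_deleted": sum(1 for r in records if r.tp53_deletion == "+"),
    }


# ---- I/O -----------------------------------------------------------------


def _parse_protein(token: str) -> str:
    token = token.strip()
    if token == "+":
        return "present"
    if token == "-":
        return "absent"
    return NOT_DETERMINED


def read_patients_csv(path: str | Path) -> list[PatientRecord]:
    """Read a patient table (columns: id, age, sex, tp53_deletion,
    protein_status (+/-/N.D), fold_expression (number or N.D), karyotype)."""
    df = pd.read_csv(path, dtype=str)
    out = []
    for r in df.itertuples():
        fold_raw = str(r.fold_expression).strip()
        fold = None if fold_raw in ("N.D", "ND", "", "nan") else float(fold_raw)
        out.append(
            PatientRecord(
                id=str(r.id),
                age=int(r.age) if str(r.age).isdigit() else None,
                sex=str(r.sex),
                tp53_deletion=str(r.tp53_deletion).strip(),
                protein_status=_parse_protein(str(r.protein_status)),
                fold_expression=fold,
                karyotype=str(r.karyotype).strip(),
            )
        )
    return out


def packaged_patient_cohort() -> list[PatientRecord]:
    """The packaged 48-patient MDS / AML-MRC cohort table."""
    ref = resources.files("pignstab.data") / "table1_patients.csv"
    with resources.as_file(ref) as path:
        return read_patients_csv(path)


def calls_table(
    records: list[PatientRecord],
    fold_up_threshold: float = DEFAULT_FOLD_THRESHOLD,
    strict: bool = False,
) -> pd.DataFrame:
    rows = []
    for r in records:
        c = classify_sample(r, fold_up_threshold, strict)
        rows.append(
            {
                "id": r.id,
                "protein_status": r.protein_status,
                "fold_expression": r.fold_expression,
                "call": c.call,
                "basis": c.basis,
            }
        )
    return pd.DataFrame(rows)
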