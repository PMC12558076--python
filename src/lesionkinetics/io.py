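"""CSV reading, schema validation, and report writing.

Two input tables are accepted, both comma-delimited with a header row and
"." as the decimal mark:

* lesion measurements: patient_id, scan_date (ISO-8601),
  d_transverse_mm, d_coronal_mm, d_sagittal_mm,
  is_conglomerate (0/1, optional, default 0)
* patients: patient_id, age, sex (female/male), symptomatic_at_dx (0/1),
  grade (1/2/3 or empty), ki67, u5hiaa, carcinoid_heart, liver_mets,
  peritoneal_mets, extraabdominal_mets, prrt_treated (all 0/1),
  mlnm_level (I/II/III_down/III_up/IV or empty),
  t_symptom_surgery_months, symptom_surgery_event (0/1),
  t_death_months, death_event (0/1)

Empty cells mean missing. Dates must be ISO-8601; durations are decimal
month offsets in explicitly *_months-named columns. Row-level problems are
collected into a single report instead of failing at the first bad cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd

from lesionkinetics.cohort import MLNM_LEVELS
from lesionkinetics.growth import GrowthEstimate
from lesionkinetics.volumetry import LesionScan

__all__ = [
    "ValidationReport",
    "read_lesion_csv",
    "read_patient_csv",
    "validate_inputs",
    "lesion_frame_to_scans",
    "growth_to_frame",
]

LESION_COLUMNS = (
    "patient_id",
    "scan_date",
    "d_transverse_mm",
    "d_coronal_mm",
    "d_sagittal_mm",
)

PATIENT_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "symptomatic_at_dx",
    "grade",
    "ki67",
    "u5hiaa",
    "carcinoid_heart",
    "liver_mets",
    "peritoneal_mets",
    "extraabdominal_mets",
    "prrt_treated",
    "mlnm_level",
    "t_symptom_surgery_months",
    "symptom_surgery_event",
    "t_death_months",
    "death_event",
)

_BOOL_COLUMNS = (
    "symptomatic_at_dx",
    "carcinoid_heart",
    "liver_mets",
    "peritoneal_mets",
    "extraabdominal_mets",
    "prrt_treated",
    "symptom_surgery_event",
    "death_event",
)


@dataclass
class ValidationReport:
    """Collected row-level errors and cross-reference warnings."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def render(self) -> str:
        lines = [f"ERROR: {e}" for e in self.errors]
        lines += [f"WARNING: {w}" for w in self.warnings]
        return "\n".join(lines) if lines else "input validation: no problems found"


def read_lesion_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in LESION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"lesion table missing required columns: {missing}")
    if "is_conglomerate" not in df.columns:
        df["is_conglomerate"] = 0
    return df


def read_patient_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "sex": str, "mlnm_level": str})
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"patient table missing required columns: {missing}")
    return df


def _validate_lesions(lesions: pd.DataFrame, report: ValidationReport) -> None:
    for idx, row in lesions.iterrows():
        rowno = idx + 2  # header is line 1
        try:
            date.fromisoformat(str(row["scan_date"]))
        except ValueError:
            report.errors.append(
                f"lesion row {rowno}: scan_date {row['scan_date']!r} is not an ISO-8601 date"
            )
        for col in ("d_transverse_mm", "d_coronal_mm", "d_sagittal_mm"):
            val = pd.to_numeric(pd.Series([row[col]]), errors="coerce").iloc[0]
            if pd.isna(val) or val <= 0:
                report.errors.append(
                    f"lesion row {rowno}: {col} must be a positive number, got {row[col]!r}"
                )
    dup = lesions.duplicated(subset=["patient_id", "scan_date"], keep=False)
    if dup.any():
        keys = lesions.loc[dup, ["patient_id", "scan_date"]].drop_duplicates()
        for _, k in keys.iterrows():
            report.errors.append(
                f"duplicate lesion key (patient_id={k['patient_id']}, scan_date={k['scan_date']})"
            )


def _validate_patients(patients: pd.DataFrame, report: ValidationReport) -> None:
    dup = patients["patient_id"].duplicated(keep=False)
    if dup.any():
        for pid in patients.loc[dup, "patient_id"].unique():
            report.errors.append(f"duplicate patient_id {pid} in patient table")
    for idx, row in patients.iterrows():
        rowno = idx + 2
        if str(row["sex"]).lower() not in ("female", "male"):
            report.errors.append(
                f"patient row {rowno}: sex must be female/male, got {row['sex']!r}"
            )
        if not pd.isna(row["grade"]) and row["grade"] not in (1, 2, 3, "1", "2", "3", 1.0, 2.0, 3.0):
            report.errors.append(
                f"patient row {rowno}: grade must be 1, 2, 3 or empty, got {row['grade']!r}"
            )
        lvl = row["mlnm_level"]
        if not pd.isna(lvl) and lvl not in MLNM_LEVELS:
            report.errors.append(
                f"patient row {rowno}: mlnm_level must be one of {MLNM_LEVELS}, got {lvl!r}"
            )
        for col in _BOOL_COLUMNS:
            if row[col] not in (0, 1, 0.0, 1.0, True, False, "0", "1"):
                report.errors.append(
                    f"patient row {rowno}: {col} must be 0/1, got {row[col]!r}"
                )
        for col in ("t_symptom_surgery_months", "t_death_months"):
            val = pd.to_numeric(pd.Series([row[col]]), errors="coerce").iloc[0]
            if pd.isna(val) or val < 0:
                report.errors.append(
                    f"patient row {rowno}: {col} must be a non-negative number, got {row[col]!r}"
                )


def validate_inputs(lesions: pd.DataFrame, patients: pd.DataFrame) -> ValidationReport:
    """Validate both tables together; never raises on bad rows.

    Hard schema problems become errors; a lesion-table patient absent from
    the patient table is a cross-reference warning only.
    """
    report = ValidationReport()
    _validate_lesions(lesions, report)
    _validate_patients(patients, report)
    orphans = sorted(set(lesions["patient_id"]) - set(patients["patient_id"]))
    for pid in orphans:
        report.warnings.append(
            f"patient {pid} appears in the lesion table but not the patient table"
        )
    return report


def lesion_frame_to_scans(lesions: pd.DataFrame) -> list[LesionScan]:
    return [
        LesionScan(
            patient_id=str(row.patient_id),
            scan_date=date.fromisoformat(str(row.scan_date)),
            d_transverse=float(row.d_transverse_mm),
            d_coronal=float(row.d_coronal_mm),
            d_sagittal=float(row.d_sagittal_mm),
            is_conglomerate=bool(row.is_conglomerate),
        )
        for row in lesions.itertuples()
    ]


def growth_to_frame(estimates: list[GrowthEstimate]) -> pd.DataFrame:
    """Growth estimates as the canonical growth CSV layout."""
    return pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "v1_mm3": e.v1,
                "v2_mm3": e.v2,
                "interval_months": e.interval_months,
                "delta_v_mm3": e.delta_v,
                "g_per_month": e.g,
                "tgr_pct_per_month": e.tgr,
                "progressed": int(e.progressed),
            }
            for e in estimates
        ],
        columns=[
            "patient_id",
            "v1_mm3",
            "v2_mm3",
            "interval_months",
            "delta_v_mm3",
            "g_per_month",
            "tgr_pct_per_month",
            "progressed",
        ],
    )
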