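"""End-to-end analysis: growth estimation plus every report table.

``run_full_analysis`` emits, in order: the growth CSV, a grouped baseline
summary, the logistic progression report, the PRRT comparison, the location
distribution, and Kaplan-Meier curve CSVs for the symptom-surgery and
overall-survival endpoints, plus a run-metadata JSON. Outputs are
bit-for-bit reproducible from the same inputs; any stage failure aborts
with the stage name and removes partial outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from lesionkinetics import __version__
from lesionkinetics.cohort import (
    fisher_exact_2x2,
    km_fit,
    location_distribution,
    logistic_progression,
    mann_whitney,
    median_iqr,
)
from lesionkinetics.growth import estimate_growth
from lesionkinetics.io import growth_to_frame, lesion_frame_to_scans
from lesionkinetics.volumetry import scans_to_volumes

__all__ = ["AnalysisRun", "StageError", "run_full_analysis", "compute_growth_table"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisRun:
    """One end-to-end analysis invocation."""

    lesion_path: Path
    patient_path: Path
    out_dir: Path
    min_interval_months: float = 2.0
    seed: int | None = None
    options: dict = field(default_factory=dict)

    def metadata(self) -> dict:
        return {
            "tool": "lesionkinetics",
            "version": __version__,
            "inputs": {
                "lesions": str(self.lesion_path),
                "patients": str(self.patient_path),
            },
            "options": {"min_interval_months": self.min_interval_months, **self.options},
            "seed": self.seed,
        }


def compute_growth_table(
    lesions: pd.DataFrame, min_interval_months: float = 2.0
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Lesion measurements -> per-patient growth CSV frame (+ exclusions)."""
    volumes = scans_to_volumes(lesion_frame_to_scans(lesions))
    estimates, excluded = estimate_growth(volumes, min_interval_months)
    return growth_to_frame(estimates), excluded


def _fmt_median_iqr(values) -> str:
    vals = pd.to_numeric(pd.Series(list(values)), errors="coerce").dropna()
    if vals.empty:
        return ""
    med, q1, q3 = median_iqr(vals)
    return f"{med:.1f} ({q1:.1f}-{q3:.1f})"


def _count_pct(mask: pd.Series, n: int) -> str:
    c = int(mask.sum())
    return f"{c} ({round(100 * c / n)})" if n else ""


def summarize_baseline(patients: pd.DataFrame) -> pd.DataFrame:
    """Grouped baseline-characteristics table (asymptomatic vs symptomatic).

    Continuous rows are median (Q1-Q3) compared by Mann-Whitney; categorical
    rows are n (percent) compared by Fisher's exact test on a 2x2 collapse
    (multi-level grade is dichotomized as grade 1 vs higher). P-values are
    blank when either group is empty.
    """
    asym = patients.loc[~patients["symptomatic_at_dx"].astype(bool)]
    sym = patients.loc[patients["symptomatic_at_dx"].astype(bool)]
    n_a, n_s = len(asym), len(sym)
    both = n_a > 0 and n_s > 0
    rows: list[dict] = []

    def continuous(label: str, col: str) -> None:
        p = ""
        a = pd.to_numeric(asym[col], errors="coerce").dropna()
        s = pd.to_numeric(sym[col], errors="coerce").dropna()
        if both and len(a) and len(s):
            p = f"{mann_whitney(a, s)[1]:.3f}"
        rows.append(
            {
                "variable": label,
                "asymptomatic": _fmt_median_iqr(asym[col]),
                "symptomatic": _fmt_median_iqr(sym[col]),
                "p_value": p,
            }
        )

    def categorical(label: str, mask_a: pd.Series, mask_s: pd.Series) -> None:
        p = ""
        if both:
            table = [
                [int(mask_a.sum()), n_a - int(mask_a.sum())],
                [int(mask_s.sum()), n_s - int(mask_s.sum())],
            ]
            p = f"{fisher_exact_2x2(table):.3f}"
        rows.append(
            {
                "variable": label,
                "asymptomatic": _count_pct(mask_a, n_a),
                "symptomatic": _count_pct(mask_s, n_s),
                "p_value": p,
            }
        )

    rows.append(
        {
            "variable": "n",
            "asymptomatic": str(n_a),
            "symptomatic": str(n_s),
            "p_value": "",
        }
    )
    continuous("age_years", "age")
    categorical(
        "sex_female",
        asym["sex"].str.lower() == "female",
        sym["sex"].str.lower() == "female",
    )
    categorical(
        "deceased", asym["death_event"].astype(bool), sym["death_event"].astype(bool)
    )
    for label, col in (
        ("liver_mets", "liver_mets"),
        ("peritoneal_mets", "peritoneal_mets"),
        ("extraabdominal_mets", "extraabdominal_mets"),
        ("carcinoid_heart", "carcinoid_heart"),
    ):
        categorical(label, asym[col].astype(bool), sym[col].astype(bool))
    continuous("u5hiaa_umol_dl", "u5hiaa")
    continuous("ki67_pct", "ki67")
    grade_a = pd.to_numeric(asym["grade"], errors="coerce")
    grade_s = pd.to_numeric(sym["grade"], errors="coerce")
    for g in (1, 2, 3):
        rows.append(
            {
                "variable": f"grade_{g}",
                "asymptomatic": _count_pct(grade_a == g, int(grade_a.notna().sum())),
                "symptomatic": _count_pct(grade_s == g, int(grade_s.notna().sum())),
                "p_value": "",
            }
        )
    if both and grade_a.notna().any() and grade_s.notna().any():
        table = [
            [int((grade_a == 1).sum()), int((grade_a > 1).sum())],
            [int((grade_s == 1).sum()), int((grade_s > 1).sum())],
        ]
        rows[-3]["p_value"] = f"{fisher_exact_2x2(table):.3f}"
    return pd.DataFrame(rows)


def compare_prrt(patients: pd.DataFrame, growth: pd.DataFrame) -> pd.DataFrame:
    """PRRT-treated vs non-treated volume change and TGR (asymptomatic only).

    Median (Q1-Q3) per group with a Mann-Whitney two-sided p-value.
    """
    asym = patients.loc[~patients["symptomatic_at_dx"].astype(bool)]
    merged = asym.merge(growth, on="patient_id", how="inner")
    treated = merged.loc[merged["prrt_treated"].astype(bool)]
    untreated = merged.loc[~merged["prrt_treated"].astype(bool)]
    rows = []
    for label, col in (("volume_change_mm3", "delta_v_mm3"), ("tgr_pct_per_month", "tgr_pct_per_month")):
        p = ""
        if len(treated) and len(untreated):
            p = f"{mann_whitney(treated[col], untreated[col])[1]:.3f}"
        rows.append(
            {
                "variable": label,
                "prrt_treated": _fmt_median_iqr(treated[col]) if len(treated) else "",
                "non_treated": _fmt_median_iqr(untreated[col]) if len(untreated) else "",
                "n_treated": len(treated),
                "n_non_treated": len(untreated),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def km_frame(patients: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    """Kaplan-Meier curve CSV frame for 'symptom' or 'os' endpoints.

    Both endpoints are estimated among patients asymptomatic at diagnosis;
    for the symptom endpoint, death and end of follow-up censor.
    """
    asym = patients.loc[~patients["symptomatic_at_dx"].astype(bool)]
    if endpoint == "symptom":
        times = pd.to_numeric(asym["t_symptom_surgery_months"])
        events = asym["symptom_surgery_event"].astype(bool)
    elif endpoint == "os":
        times = pd.to_numeric(asym["t_death_months"])
        events = asym["death_event"].astype(bool)
    else:
        raise ValueError(f"unknown endpoint {endpoint!r}; expected 'symptom' or 'os'")
    curve = km_fit(times.to_numpy(), events.to_numpy())
    return curve.to_frame()


def logit_frame(patients: pd.DataFrame, growth: pd.DataFrame) -> pd.DataFrame:
    fit = logistic_progression(patients, growth)
    frame = fit.to_frame()
    frame["n_used"] = fit.n_used
    frame["n_excluded"] = fit.n_excluded_total
    return frame


_OUTPUTS = (
    "growth.csv",
    "summary.csv",
    "logistic.csv",
    "prrt_comparison.csv",
    "locations.csv",
    "km_symptom.csv",
    "km_os.csv",
)


def run_full_analysis(
    run: AnalysisRun, lesions: pd.DataFrame, patients: pd.DataFrame
) -> list[Path]:
    """Execute every stage and write all report CSVs plus run metadata.

    Returns the written paths. On any stage failure, removes files already
    written in this run and raises StageError naming the stage.
    """
    out = Path(run.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = out / name
        frame.to_csv(path, index=False, float_format="%.10g")
        written.append(path)
        logger.info("wrote %s (%d rows)", path, len(frame))

    try:
        stage = "growth"
        growth, excluded = compute_growth_table(lesions, run.min_interval_months)
        for pid, reason in excluded.items():
            logger.info("excluded patient %s: %s", pid, reason)
        emit("growth.csv", growth)

        stage = "summary"
        emit("summary.csv", summarize_baseline(patients))

        stage = "logistic"
        emit("logistic.csv", logit_frame(patients, growth))

        stage = "prrt_comparison"
        emit("prrt_comparison.csv", compare_prrt(patients, growth))

        stage = "locations"
        emit("locations.csv", location_distribution(patients))

        stage = "km_symptom"
        emit("km_symptom.csv", km_frame(patients, "symptom"))

        stage = "km_os"
        emit("km_os.csv", km_frame(patients, "os"))

        stage = "metadata"
        meta_path = out / "run_metadata.json"
        meta = run.metadata()
        meta["outputs"] = [p.name for p in written]
        meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
        written.append(meta_path)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise StageError(stage, exc) from exc
    return written
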