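"""Exponential growth kinetics from paired baseline/follow-up volumes.

Assuming roughly exponential growth V2 = V1 * exp(g * t) with t in months,
the growth constant is g = ln(V2/V1) / t and the tumor growth rate is

    TGR = 100 * (exp(g) - 1)     [% volume change per month]

Equivalently, in terms of effective diameters d = (6V/pi)^(1/3),
g = 3 * ln(d2/d1) / t. A month is 30.4375 days (365.25 / 12).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date

from lesionkinetics.volumetry import LesionVolume, ValidationError

__all__ = [
    "DAYS_PER_MONTH",
    "GrowthEstimate",
    "growth_constant",
    "tumor_growth_rate",
    "months_between",
    "estimate_growth",
    "classify_progression",
]

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.4375  # 365.25 / 12


@dataclass(frozen=True)
class GrowthEstimate:
    """Paired-scan kinetics for one patient.

    ``v1`` is the baseline (earliest) volume, ``v2`` the most recent, both
    mm^3; ``g`` is the per-month exponential growth constant, ``tgr`` the
    growth rate in % per month, and ``progressed`` is true iff the volume
    strictly increased.
    """

    patient_id: str
    v1: float
    v2: float
    interval_months: float
    delta_v: float
    g: float
    tgr: float
    progressed: bool


def growth_constant(v1: float, v2: float, t: float) -> float:
    """Per-month exponential growth constant g with v2 = v1 * exp(g * t).

    Parameters
    ----------
    v1, v2
        Baseline and follow-up volumes (mm^3), strictly positive.
    t
        Interval in months, strictly positive.
    """
    if not (math.isfinite(v1) and v1 > 0):
        raise ValidationError(f"v1 must be strictly positive, got {v1!r}")
    if not (math.isfinite(v2) and v2 > 0):
        raise ValidationError(f"v2 must be strictly positive, got {v2!r}")
    if not (math.isfinite(t) and t > 0):
        raise ValidationError(f"interval t must be strictly positive months, got {t!r}")
    return math.log(v2 / v1) / t


def tumor_growth_rate(g: float) -> float:
    """Tumor growth rate in % volume change per month: 100 * (exp(g) - 1).

    Strictly increasing in ``g`` and bounded below by -100.
    """
    if not math.isfinite(g):
        raise ValidationError(f"growth constant must be finite, got {g!r}")
    return 100.0 * math.expm1(g)


def months_between(date1: date, date2: date) -> float:
    """Interval from ``date1`` to ``date2`` in months of 30.4375 days."""
    if date2 < date1:
        raise ValidationError(
            f"date2 ({date2.isoformat()}) precedes date1 ({date1.isoformat()})"
        )
    return (date2 - date1).days / DAYS_PER_MONTH


def classify_progression(estimate: GrowthEstimate) -> bool:
    """True iff the volume strictly increased (delta_v > 0, i.e. tgr > 0)."""
    return estimate.delta_v > 0


def estimate_growth(
    volumes: list[LesionVolume],
    min_interval_months: float = 2.0,
) -> tuple[list[GrowthEstimate], dict[str, str]]:
    """Per-patient growth estimates from serial lesion volumes.

    For each patient the earliest scan is the baseline (V1) and the latest
    the most recent follow-up (V2); intermediate scans are ignored. Patients
    with fewer than two distinct scan dates are skipped with a warning, and
    patients whose baseline-to-last interval is below ``min_interval_months``
    are excluded.

    Returns
    -------
    (estimates, excluded)
        ``estimates`` sorted by patient id; ``excluded`` maps each skipped
        patient id to the reason it was dropped.
    """
    by_patient: dict[str, list[LesionVolume]] = {}
    for vol in volumes:
        by_patient.setdefault(vol.patient_id, []).append(vol)

    estimates: list[GrowthEstimate] = []
    excluded: dict[str, str] = {}
    for patient_id in sorted(by_patient):
        series = sorted(by_patient[patient_id], key=lambda v: v.scan_date)
        if len(series) < 2 or series[0].scan_date == series[-1].scan_date:
            excluded[patient_id] = "fewer than 2 scans on distinct dates"
            logger.warning("patient %s skipped: %s", patient_id, excluded[patient_id])
            continue
        first, last = series[0], series[-1]
        t = months_between(first.scan_date, last.scan_date)
        if t < min_interval_months:
            excluded[patient_id] = (
                f"interval {t:.2f} months below minimum {min_interval_months:g}"
            )
            logger.warning("patient %s excluded: %s", patient_id, excluded[patient_id])
            continue
        g = growth_constant(first.volume, last.volume, t)
        est = GrowthEstimate(
            patient_id=patient_id,
            v1=first.volume,
            v2=last.volume,
            interval_months=t,
            delta_v=last.volume - first.volume,
            g=g,
            tgr=tumor_growth_rate(g),
            progressed=last.volume - first.volume > 0,
        )
        estimates.append(est)
    return estimates, excluded
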