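"""Ellipsoid volumetry from tri-planar lesion diameter measurements.

A lesion measured in the transverse, coronal and sagittal planes is treated
as an ellipsoid whose three principal diameters are the planar maximal
diameters; semi-axes are diameters / 2, so

    V = (4/3) * pi * (d1/2) * (d2/2) * (d3/2) = (pi/6) * d1 * d2 * d3.

Conglomerate lesion clusters measured as a single entity carry a flag but
are computed identically. All lengths are millimetres; volumes are mm^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date

__all__ = ["LesionScan", "LesionVolume", "ellipsoid_volume", "scans_to_volumes"]


class ValidationError(ValueError):
    """An input value violates a field-level contract."""


def _check_diameter(value: float, field: str) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0:
        raise ValidationError(
            f"{field} must be a strictly positive finite length in mm, got {value!r}"
        )
    return value


@dataclass(frozen=True)
class LesionScan:
    """One lesion measurement at one scan date.

    Diameters are full maximal diameters (mm) in the transverse, coronal and
    sagittal planes. ``is_conglomerate`` marks a lymph-node cluster measured
    as a single entity; it does not change the volume computation.
    """

    patient_id: str
    scan_date: date
    d_transverse: float
    d_coronal: float
    d_sagittal: float
    is_conglomerate: bool = False

    def __post_init__(self) -> None:
        _check_diameter(self.d_transverse, "d_transverse")
        _check_diameter(self.d_coronal, "d_coronal")
        _check_diameter(self.d_sagittal, "d_sagittal")
        if not isinstance(self.scan_date, date):
            raise ValidationError(
                f"scan_date must be a datetime.date, got {type(self.scan_date).__name__}"
            )


@dataclass(frozen=True)
class LesionVolume:
    """Ellipsoid volume (mm^3) of one lesion at one scan date."""

    patient_id: str
    scan_date: date
    volume: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.volume) or self.volume <= 0:
            raise ValidationError(f"volume must be strictly positive, got {self.volume!r}")


def ellipsoid_volume(d1: float, d2: float, d3: float) -> float:
    """Ellipsoid volume (mm^3) from three orthogonal maximal diameters (mm).

    Semi-axes are half the diameters, giving V = (pi/6) * d1 * d2 * d3.
    Symmetric under any permutation of the arguments.

    Parameters
    ----------
    d1, d2, d3
        Full diameters along the three principal axes, in mm. Must be
        strictly positive and finite.

    Returns
    -------
    float
        Volume in mm^3.

    Examples
    --------
    >>> round(ellipsoid_volume(10, 10, 10), 4)
    523.5988
    """
    d1 = _check_diameter(d1, "d1")
    d2 = _check_diameter(d2, "d2")
    d3 = _check_diameter(d3, "d3")
    # multiply in sorted order so the result is bit-identical under any
    # permutation of the arguments
    a, b, c = sorted((d1, d2, d3))
    return (math.pi / 6.0) * a * b * c


def scans_to_volumes(scans: list[LesionScan]) -> list[LesionVolume]:
    """Convert lesion scans to ellipsoid volumes, one per (patient, date).

    Parameters
    ----------
    scans
        Lesion measurements, at most one per patient per scan date.

    Returns
    -------
    list of LesionVolume
        One volume per input scan, in input order.

    Raises
    ------
    ValidationError
        If any (patient_id, scan_date) pair occurs more than once; the
        message lists every duplicate key.
    """
    seen: set[tuple[str, date]] = set()
    duplicates: list[tuple[str, date]] = []
    for scan in scans:
        key = (scan.patient_id, scan.scan_date)
        if key in seen:
            duplicates.append(key)
        seen.add(key)
    if duplicates:
        listed = ", ".join(f"({pid}, {d.isoformat()})" for pid, d in duplicates)
        raise ValidationError(f"duplicate (patient_id, scan_date) keys: {listed}")
    return [
        LesionVolume(
            patient_id=scan.patient_id,
            scan_date=scan.scan_date,
            volume=ellipsoid_volume(scan.d_transverse, scan.d_coronal, scan.d_sagittal),
        )
        for scan in scans
    ]
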