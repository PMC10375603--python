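"""Output factors and their field-size-dependent tolerance checks.

The output factor is the ratio of the absorbed dose for a field size to
that of the 10x10 cm2 reference field at the reference depth.  The
tolerance is 1% at and above 5x5 cm2 and 2% for small (<= 4x4 cm2)
fields.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import AnalysisError

SMALL_FIELD_LIMIT_MM = 40.0
SMALL_FIELD_TOL_PCT = 2.0
STANDARD_TOL_PCT = 1.0


def output_factor(dose_field: float, dose_reference: float) -> float:
    """Dose ratio field/reference, reported to 3 decimals."""
    if dose_field <= 0 or dose_reference <= 0:
        raise AnalysisError("output factor readings must be > 0")
    return round(dose_field / dose_reference, 3)


def of_tolerance_pct(field_mm: float) -> float:
    """Applicable tolerance for a square field of the given side (mm)."""
    if field_mm <= 0:
        raise AnalysisError("field size must be > 0")
    return SMALL_FIELD_TOL_PCT if field_mm <= SMALL_FIELD_LIMIT_MM else STANDARD_TOL_PCT


@dataclass(frozen=True)
class OutputFactorRecord:
    field_mm: float
    of_value: float
    reference_of: float
    deviation_pct: float
    tolerance_pct: float
    verdict: str

    def to_dict(self) -> dict:
        return {
            "field_mm": self.field_mm,
            "of_value": round(self.of_value, 3),
            "reference_of": round(self.reference_of, 3),
            "deviation_pct": round(self.deviation_pct, 2),
            "tolerance_pct": self.tolerance_pct,
            "verdict": self.verdict,
        }


def of_tolerance_check(record: OutputFactorRecord) -> str:
    """'pass' when the deviation stays within the field-size tolerance."""
    return "pass" if abs(record.deviation_pct) <= record.tolerance_pct else "fail"


def make_of_record(field_mm: float, of_value: float,
                   reference_of: float) -> OutputFactorRecord:
    if of_value <= 0 or reference_of <= 0:
        raise AnalysisError("output factors must be > 0")
    deviation = 100.0 * (of_value - reference_of) / reference_of
    tol = of_tolerance_pct(field_mm)
    rec = OutputFactorRecord(
        field_mm=field_mm,
        of_value=of_value,
        reference_of=reference_of,
        deviation_pct=deviation,
        tolerance_pct=tol,
        verdict="pending",
    )
    return replace(rec, verdict=of_tolerance_check(rec))


def output_factor_table(readings: dict[float, float],
                        reference_field_mm: float = 100.0,
                        reference_readings: dict[float, float] | None = None
                        ) -> list[OutputFactorRecord]:
    """Build OF records from raw readings keyed by field side (mm).

    ``reference_readings`` supplies the baseline machine; when omitted
    the measured OFs are compared against themselves (deviation 0).
    """
    if reference_field_mm not in readings:
        raise AnalysisError(
            f"missing reading for the reference field {reference_field_mm:g} mm"
        )
    ref_dose = readings[reference_field_mm]
    records = []
    for field_mm in sorted(readings):
        of = output_factor(readings[field_mm], ref_dose)
        if reference_readings is not None:
            if field_mm not in reference_readings or \
                    reference_field_mm not in reference_readings:
                raise AnalysisError(
                    f"missing baseline reading for field {field_mm:g} mm"
                )
            ref_of = output_factor(
                reference_readings[field_mm],
                reference_readings[reference_field_mm],
            )
        else:
            ref_of = of
        records.append(make_of_record(field_mm, of, ref_of))
    return records
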