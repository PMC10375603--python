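"""Deviation-from-baseline audit: tolerance verdicts and report bundles.

Sign convention is measured - reference throughout.  Deviations are
computed on unrounded values and rounded only for display; the JSON
bundle additionally stores full precision.  Report regeneration is
byte-identical for identical inputs (stable ordering, fixed rounding).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

from .beam_io import ScanCurve, ScanSet
from .errors import AnalysisError, ValidationError
from .gamma1d import GammaCriteria
from .pdd_metrics import find_dmax, pdd_at_depth
from .profile_metrics import profile_metrics

SCHEMA_VERSION = "1.0"

MODE_RELATIVE = "relative_pct"
MODE_ABSOLUTE_MM = "absolute_mm"
MODE_ABSOLUTE_PP = "absolute_pct_points"
_MODES = (MODE_RELATIVE, MODE_ABSOLUTE_MM, MODE_ABSOLUTE_PP)


@dataclass(frozen=True)
class ToleranceSpec:
    """Study and vendor limits for one audited parameter."""

    parameter: str
    mode: str
    study_limit: float
    vendor_limit: float

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValidationError(f"unknown tolerance mode {self.mode!r}")
        if not (self.study_limit > 0 and self.vendor_limit > 0):
            raise ValidationError("tolerance limits must be > 0")
        if self.study_limit > self.vendor_limit:
            raise ValidationError("study limit must not exceed the vendor limit")


def default_tolerances() -> dict[str, ToleranceSpec]:
    return {
        "dmax": ToleranceSpec("dmax", MODE_ABSOLUTE_MM, 1.0, 1.0),
        "pdd10": ToleranceSpec("pdd10", MODE_RELATIVE, 1.0, 1.0),
        "flatness": ToleranceSpec("flatness", MODE_RELATIVE, 1.0, 2.0),
        "unflatness": ToleranceSpec("unflatness", MODE_RELATIVE, 1.0, 2.0),
        "symmetry": ToleranceSpec("symmetry", MODE_RELATIVE, 1.0, 2.0),
        "penumbra": ToleranceSpec("penumbra", MODE_ABSOLUTE_MM, 1.0, 1.0),
    }


@dataclass(frozen=True)
class AuditConfig:
    """Tolerance tables plus gamma criteria for an audit run."""

    tolerances: Mapping[str, ToleranceSpec] = field(default_factory=default_tolerances)
    gamma_study: GammaCriteria = field(default_factory=lambda: GammaCriteria(1.0, 1.0))
    gamma_vendor: GammaCriteria = field(default_factory=lambda: GammaCriteria(2.0, 2.0))
    gamma_psqa: GammaCriteria = field(default_factory=lambda: GammaCriteria(3.0, 3.0))
    psqa_action_pct: float = 95.0

    @classmethod
    def from_yaml(cls, path) -> "AuditConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        tols = default_tolerances()
        for name, entry in (raw.get("tolerances") or {}).items():
            tols[name] = ToleranceSpec(
                parameter=name,
                mode=entry.get("mode", MODE_RELATIVE),
                study_limit=float(entry["study"]),
                vendor_limit=float(entry["vendor"]),
            )

        def crit(key: str, default: GammaCriteria) -> GammaCriteria:
            entry = (raw.get("gamma") or {}).get(key)
            if entry is None:
                return default
            return GammaCriteria(
                dd_pct=float(entry["dd_pct"]),
                dta_mm=float(entry["dta_mm"]),
                threshold_pct=float(entry.get("threshold_pct", 0.0)),
            )

        return cls(
            tolerances=tols,
            gamma_study=crit("study", GammaCriteria(1.0, 1.0)),
            gamma_vendor=crit("vendor", GammaCriteria(2.0, 2.0)),
            gamma_psqa=crit("psqa", GammaCriteria(3.0, 3.0)),
            psqa_action_pct=float(raw.get("psqa_action_pct", 95.0)),
        )


@dataclass(frozen=True)
class AuditRecord:
    """One measured-vs-reference comparison with its verdicts."""

    machine_id: str
    parameter: str
    field_mm: float
    depth_mm: float | None
    axis: str
    measured: float
    reference: float
    deviation: float
    study_verdict: str = "pending"
    vendor_verdict: str = "pending"

    def to_dict(self) -> dict:
        return {
            "machine_id": self.machine_id,
            "parameter": self.parameter,
            "field_mm": self.field_mm,
            "depth_mm": self.depth_mm,
            "axis": self.axis,
            "measured": self.measured,
            "reference": self.reference,
            "deviation": self.deviation,
            "deviation_display": round(self.deviation, 2),
            "study_verdict": self.study_verdict,
            "vendor_verdict": self.vendor_verdict,
        }


# --------------------------------------------------------------------------
# deviation arithmetic
# --------------------------------------------------------------------------

def percent_deviation(measured: float, reference: float) -> float:
    """Signed 100*(measured - reference)/reference."""
    if reference == 0:
        raise AnalysisError("zero reference value")
    return 100.0 * (measured - reference) / reference


def absolute_deviation(measured: float, reference: float) -> float:
    """Signed measured - reference (mm or percent points)."""
    return measured - reference


def evaluate_tolerance(deviation: float, spec: ToleranceSpec) -> tuple[str, str]:
    """(study_verdict, vendor_verdict): pass iff |deviation| <= limit."""
    study = "pass" if abs(deviation) <= spec.study_limit else "fail"
    vendor = "pass" if abs(deviation) <= spec.vendor_limit else "fail"
    return study, vendor


def max_abs_deviation(records: Sequence[AuditRecord]) -> AuditRecord:
    """Record with the largest |deviation|; ties keep the first."""
    if not records:
        raise AnalysisError("empty record list")
    best = records[0]
    for rec in records[1:]:
        if abs(rec.deviation) > abs(best.deviation):
            best = rec
    return best


def aggregate_pass_rates(per_plan: Mapping[str, float],
                         group: Iterable[str] | None = None) -> float:
    """Arithmetic mean of per-plan gamma pass rates over ``group``
    (all plans when omitted)."""
    keys = list(per_plan) if group is None else list(group)
    if not keys:
        raise AnalysisError("empty plan group")
    missing = [k for k in keys if k not in per_plan]
    if missing:
        raise AnalysisError(f"unknown plans in group: {missing}")
    return sum(per_plan[k] for k in keys) / len(keys)


def literature_diff(measured_mm, reported_mm: float) -> float:
    """Signed measured - reported (mm).

    ``measured_mm`` is either a single plane-specific value or an
    (in-plane, cross-plane) pair, in which case their mean is used.
    """
    if isinstance(measured_mm, (tuple, list)):
        measured = sum(float(v) for v in measured_mm) / len(measured_mm)
    else:
        measured = float(measured_mm)
    if measured <= 0 or reported_mm <= 0:
        raise AnalysisError("penumbra values must be > 0")
    return measured - float(reported_mm)


# --------------------------------------------------------------------------
# report building
# --------------------------------------------------------------------------

def curve_parameter_values(curve: ScanCurve) -> dict[str, float]:
    """Audited parameters extracted from one curve.

    Depth scans yield dmax and pdd10; profiles yield symmetry, the
    average penumbra, and flatness (FF) or unflatness (FFF).
    """
    if not curve.is_profile:
        return {
            "dmax": find_dmax(curve),
            "pdd10": pdd_at_depth(curve, 100.0),
        }
    pm = profile_metrics(curve)
    out = {"symmetry": pm.symmetry_pct, "penumbra": pm.penumbra_avg_mm}
    if curve.spec.fff:
        out["unflatness"] = pm.unflatness
    else:
        out["flatness"] = pm.flatness_pct
    return out


def _curve_key(curve: ScanCurve, parameter: str) -> tuple:
    s = curve.spec
    return (
        parameter,
        bool(s.fff),
        s.scan_axis,
        float(s.nominal_field_mm),
        None if s.depth_mm is None else float(s.depth_mm),
    )


def baseline_table(scans: ScanSet) -> dict[tuple, float]:
    """Parameter table extracted from a baseline (reference) scan set."""
    if len(scans) == 0:
        raise AnalysisError("empty baseline scan set")
    table: dict[tuple, float] = {}
    for curve in scans:
        for parameter, value in curve_parameter_values(curve).items():
            table[_curve_key(curve, parameter)] = value
    return table


def _group_by_machine(scans) -> dict[str, ScanSet]:
    if isinstance(scans, ScanSet):
        grouped: dict[str, list[ScanCurve]] = {}
        for curve in scans:
            grouped.setdefault(curve.spec.machine_id, []).append(curve)
        return {m: ScanSet(tuple(cs)) for m, cs in grouped.items()}
    return dict(scans)


def build_audit_report(scans, baselines, config: AuditConfig | None = None) -> dict:
    """Full audit bundle: per-parameter records, verdicts and summary.

    ``scans`` is a mapping machine_id -> ScanSet (or one ScanSet whose
    curves carry their machine in the header); ``baselines`` is either a
    reference ScanSet or an already-extracted parameter table keyed as
    produced by :func:`baseline_table`.
    """
    cfg = config or AuditConfig()
    by_machine = _group_by_machine(scans)
    if not by_machine or all(len(ss) == 0 for ss in by_machine.values()):
        raise AnalysisError("empty scan set")
    table = baseline_table(baselines) if isinstance(baselines, ScanSet) else dict(baselines)

    records: list[AuditRecord] = []
    for machine_id in sorted(by_machine):
        scan_set = by_machine[machine_id]
        if len(scan_set) == 0:
            raise AnalysisError(f"empty scan set for machine {machine_id}")
        for curve in scan_set:
            for parameter, measured in curve_parameter_values(curve).items():
                key = _curve_key(curve, parameter)
                if key not in table:
                    raise AnalysisError(f"missing baseline entry for key {key}")
                reference = table[key]
                if parameter not in cfg.tolerances:
                    raise AnalysisError(f"no tolerance configured for {parameter!r}")
                spec = cfg.tolerances[parameter]
                if spec.mode == MODE_RELATIVE:
                    deviation = percent_deviation(measured, reference)
                else:
                    deviation = absolute_deviation(measured, reference)
                study, vendor = evaluate_tolerance(deviation, spec)
                records.append(AuditRecord(
                    machine_id=machine_id,
                    parameter=parameter,
                    field_mm=float(curve.spec.nominal_field_mm),
                    depth_mm=(None if curve.spec.depth_mm is None
                              else float(curve.spec.depth_mm)),
                    axis=curve.spec.scan_axis,
                    measured=measured,
                    reference=reference,
                    deviation=deviation,
                    study_verdict=study,
                    vendor_verdict=vendor,
                ))

    records.sort(key=lambda r: (r.machine_id, r.parameter, r.field_mm,
                                -1.0 if r.depth_mm is None else r.depth_mm, r.axis))
    by_parameter: dict[str, list[AuditRecord]] = {}
    for rec in records:
        by_parameter.setdefault(rec.parameter, []).append(rec)
    worst = {
        parameter: round(max_abs_deviation(recs).deviation, 4)
        for parameter, recs in sorted(by_parameter.items())
    }
    n_study_fail = sum(1 for r in records if r.study_verdict == "fail")
    n_vendor_fail = sum(1 for r in records if r.vendor_verdict == "fail")
    return {
        "schema_version": SCHEMA_VERSION,
        "records": [r.to_dict() for r in records],
        "summary": {
            "n_machines": len(by_machine),
            "n_records": len(records),
            "n_study_fail": n_study_fail,
            "n_vendor_fail": n_vendor_fail,
            "all_study_pass": n_study_fail == 0,
            "worst_deviation_by_parameter": worst,
        },
    }


# --------------------------------------------------------------------------
# emission
# --------------------------------------------------------------------------

_CSV_COLUMNS = ("machine_id", "parameter", "field_mm", "depth_mm", "axis",
                "measured", "reference", "deviation_display",
                "study_verdict", "vendor_verdict")


def report_to_json(bundle: dict) -> str:
    return json.dumps(bundle, indent=2, sort_keys=True) + "\n"


def report_to_csv(bundle: dict) -> str:
    lines = [",".join(_CSV_COLUMNS)]
    for rec in bundle["records"]:
        cells = []
        for col in _CSV_COLUMNS:
            v = rec[col]
            if v is None:
                cells.append("")
            elif isinstance(v, float):
                cells.append(format(round(v, 4), "g"))
            else:
                cells.append(str(v))
        lines.append(",".join(cells))
    return "\n".join(lines) + "\n"


def report_to_markdown(bundle: dict) -> str:
    head = "| " + " | ".join(_CSV_COLUMNS) + " |"
    sep = "|" + "|".join(["---"] * len(_CSV_COLUMNS)) + "|"
    lines = [
        f"# Beam-matching audit report (schema {bundle['schema_version']})",
        "",
        head,
        sep,
    ]
    for rec in bundle["records"]:
        cells = []
        for col in _CSV_COLUMNS:
            v = rec[col]
            if v is None:
                cells.append("")
            elif isinstance(v, float):
                cells.append(format(round(v, 4), "g"))
            else:
                cells.append(str(v))
        lines.append("| " + " | ".join(cells) + " |")
    s = bundle["summary"]
    lines += [
        "",
        f"Records: {s['n_records']}  |  study failures: {s['n_study_fail']}"
        f"  |  vendor failures: {s['n_vendor_fail']}",
        "",
    ]
    return "\n".join(lines)
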