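"""Plain-text scan-curve I/O.

Scan dialect
------------
A scan file holds one or more curve blocks separated by blank lines.
Each block starts with ``# key: value`` header lines followed by a CSV
body ``position_mm,dose`` (the column-title row is written on output and
tolerated on input).  Mandatory header keys: ``machine_id``,
``energy_MV``, ``fff``, ``field_x_mm``, ``field_y_mm``, ``ssd_mm``,
``scan_axis``; ``depth_mm`` is mandatory for profile scans
(``scan_axis`` in {crossplane, inplane}) and must be absent for depth
scans.  Optional keys: ``detector``, ``date``, ``comment``.

Positions are millimetres everywhere; off-axis coordinates are signed
(negative = toward the gun for in-plane scans, toward the A bank for
cross-plane scans).  Dose values are kept exactly as written — the
reader/writer never normalizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ScanFormatError, ValidationError

SCAN_AXES = ("crossplane", "inplane", "depth")

MANDATORY_HEADER_KEYS = (
    "machine_id",
    "energy_MV",
    "fff",
    "field_x_mm",
    "field_y_mm",
    "ssd_mm",
    "scan_axis",
)
OPTIONAL_HEADER_KEYS = ("depth_mm", "detector", "date", "comment")

_COLUMN_TITLE = "position_mm,dose"


@dataclass(frozen=True)
class BeamSpec:
    """Metadata identifying one scanned beam/geometry."""

    machine_id: str
    energy_MV: float
    fff: bool
    field_x_mm: float
    field_y_mm: float
    ssd_mm: float
    scan_axis: str
    depth_mm: float | None = None
    detector: str = ""
    date: str = ""
    comment: str = ""

    def __post_init__(self) -> None:
        if self.scan_axis not in SCAN_AXES:
            raise ValidationError(
                f"scan_axis must be one of {SCAN_AXES}, got {self.scan_axis!r}"
            )
        for name in ("energy_MV", "field_x_mm", "field_y_mm", "ssd_mm"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if self.scan_axis == "depth":
            if self.depth_mm is not None:
                raise ValidationError("depth_mm must be absent for depth scans")
        else:
            if self.depth_mm is None:
                raise ValidationError("depth_mm is required for profile scans")
            if not self.depth_mm > 0:
                raise ValidationError("depth_mm must be > 0")

    @property
    def is_profile(self) -> bool:
        return self.scan_axis != "depth"

    @property
    def nominal_field_mm(self) -> float:
        """Nominal field side along the scanned axis (x for cross-plane)."""
        return self.field_y_mm if self.scan_axis == "inplane" else self.field_x_mm


@dataclass(frozen=True)
class ScanCurve:
    """One measured curve: strictly increasing positions plus doses."""

    spec: BeamSpec
    positions: np.ndarray
    doses: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float).copy()
        d = np.asarray(self.doses, dtype=float).copy()
        if p.ndim != 1 or d.ndim != 1:
            raise ValidationError("positions and doses must be 1-D")
        if p.size != d.size:
            raise ValidationError(
                f"position/dose length mismatch: {p.size} vs {d.size}"
            )
        if p.size < 5:
            raise ValidationError("curve must contain at least 5 samples")
        if not np.all(np.diff(p) > 0):
            raise ValidationError("non-monotonic positions")
        if np.any(d < 0):
            raise ValidationError("doses must be >= 0")
        if not np.any(d > 0):
            raise ValidationError("all-zero dose vector")
        if self.spec.is_profile:
            if not (p[0] < 0.0 < p[-1]):
                raise ValidationError(
                    "profile positions must span both sides of the axis"
                )
        else:
            if p[0] < 0:
                raise ValidationError("depth positions must be >= 0")
        p.flags.writeable = False
        d.flags.writeable = False
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "doses", d)

    @property
    def n(self) -> int:
        return int(self.positions.size)

    @property
    def is_profile(self) -> bool:
        return self.spec.is_profile

    def with_doses(self, doses: np.ndarray) -> "ScanCurve":
        return ScanCurve(self.spec, self.positions, doses)

    def with_positions(self, positions: np.ndarray) -> "ScanCurve":
        return ScanCurve(self.spec, positions, self.doses)

    def dose_at(self, position_mm: float) -> float:
        """Linear interpolation; raises if outside the sampled range."""
        p = self.positions
        if not (p[0] <= position_mm <= p[-1]):
            raise ValidationError(
                f"position {position_mm} mm outside scan range [{p[0]}, {p[-1]}]"
            )
        return float(np.interp(position_mm, p, self.doses))


@dataclass(frozen=True)
class ScanSet:
    """A parsed collection of curves plus provenance of where they came from."""

    curves: tuple[ScanCurve, ...]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "curves", tuple(self.curves))
        for c in self.curves:
            if not isinstance(c, ScanCurve):
                raise ValidationError("ScanSet curves must be ScanCurve instances")

    def __len__(self) -> int:
        return len(self.curves)

    def __iter__(self):
        return iter(self.curves)


def _fmt(value: float) -> str:
    return format(float(value), ".9g")


def _parse_float(text: str, line_no: int, what: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ScanFormatError(f"cannot parse {what} {text!r} as a number", line=line_no)


def _parse_bool(text: str, line_no: int) -> bool:
    low = text.strip().lower()
    if low in ("true", "1", "yes"):
        return True
    if low in ("false", "0", "no"):
        return False
    raise ScanFormatError(f"cannot parse fff flag {text!r}", line=line_no)


def _parse_block(lines: list[tuple[int, str]], index: int) -> ScanCurve:
    headers: dict[str, str] = {}
    header_lines: dict[str, int] = {}
    body_start = None
    for i, (line_no, text) in enumerate(lines):
        if text.startswith("#"):
            payload = text[1:].strip()
            if ":" not in payload:
                raise ScanFormatError(
                    f"malformed header line {text!r} (expected '# key: value')",
                    line=line_no,
                )
            key, value = payload.split(":", 1)
            headers[key.strip()] = value.strip()
            header_lines[key.strip()] = line_no
        else:
            body_start = i
            break
    if body_start is None:
        raise ScanFormatError(
            f"curve {index}: block has headers but no data rows", line=lines[0][0]
        )

    first_line = lines[0][0]
    for key in MANDATORY_HEADER_KEYS:
        if key not in headers:
            raise ScanFormatError(
                f"missing mandatory header key '{key}' in curve block {index}",
                line=first_line,
            )
    axis = headers["scan_axis"]
    if axis not in SCAN_AXES:
        raise ScanFormatError(
            f"unknown scan_axis {axis!r}", line=header_lines["scan_axis"]
        )
    if axis != "depth" and "depth_mm" not in headers:
        raise ScanFormatError(
            f"missing mandatory header key 'depth_mm' for profile curve block {index}",
            line=first_line,
        )

    hline = header_lines
    spec_kwargs = dict(
        machine_id=headers["machine_id"],
        energy_MV=_parse_float(headers["energy_MV"], hline["energy_MV"], "energy_MV"),
        fff=_parse_bool(headers["fff"], hline["fff"]),
        field_x_mm=_parse_float(
            headers["field_x_mm"], hline["field_x_mm"], "field_x_mm"
        ),
        field_y_mm=_parse_float(
            headers["field_y_mm"], hline["field_y_mm"], "field_y_mm"
        ),
        ssd_mm=_parse_float(headers["ssd_mm"], hline["ssd_mm"], "ssd_mm"),
        scan_axis=axis,
        depth_mm=(
            _parse_float(headers["depth_mm"], hline["depth_mm"], "depth_mm")
            if "depth_mm" in headers
            else None
        ),
        detector=headers.get("detector", ""),
        date=headers.get("date", ""),
        comment=headers.get("comment", ""),
    )

    positions: list[float] = []
    doses: list[float] = []
    for line_no, text in lines[body_start:]:
        if text.strip() == _COLUMN_TITLE:
            continue
        parts = text.split(",")
        if len(parts) != 2:
            raise ScanFormatError(
                f"expected 'position_mm,dose' row, got {text!r}", line=line_no
            )
        positions.append(_parse_float(parts[0], line_no, "position"))
        doses.append(_parse_float(parts[1], line_no, "dose"))

    try:
        spec = BeamSpec(**spec_kwargs)
        return ScanCurve(spec, np.asarray(positions), np.asarray(doses))
    except ValidationError as exc:
        raise ValidationError(
            f"curve {index} (starting line {first_line}): {exc}"
        ) from exc


def read_scan_file(path) -> ScanSet:
    """Parse a scan file into a :class:`ScanSet`.

    Raises :class:`ScanFormatError` for dialect violations (with line
    numbers) and :class:`ValidationError` for curves that parse but
    violate curve invariants.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = fh.readlines()

    blocks: list[list[tuple[int, str]]] = []
    current: list[tuple[int, str]] = []
    for line_no, line in enumerate(raw, start=1):
        text = line.rstrip("\n")
        if text.strip() == "":
            if current:
                blocks.append(current)
                current = []
        else:
            current.append((line_no, text))
    if current:
        blocks.append(current)
    if not blocks:
        raise ScanFormatError(f"no curve blocks found in {path}")

    curves = []
    log = []
    for i, block in enumerate(blocks, start=1):
        curve = _parse_block(block, i)
        curves.append(curve)
        log.append(
            f"curve {i}: lines {block[0][0]}-{block[-1][0]} ({curve.n} samples)"
        )
    return ScanSet(tuple(curves), provenance={"path": str(path), "log": tuple(log)})


def write_scan_file(scans: ScanSet, path) -> str:
    """Write a ScanSet in the scan dialect; returns the path written.

    Round-trip guarantee: re-reading reproduces positions and doses to
    at least 9 significant digits and metadata exactly.  Dose values are
    written unchanged (raw detector units stay raw).
    """
    if len(scans) == 0:
        raise ValidationError("empty scan set")
    lines: list[str] = []
    for curve in scans:
        s = curve.spec
        lines.append(f"# machine_id: {s.machine_id}")
        lines.append(f"# energy_MV: {_fmt(s.energy_MV)}")
        lines.append(f"# fff: {'true' if s.fff else 'false'}")
        lines.append(f"# field_x_mm: {_fmt(s.field_x_mm)}")
        lines.append(f"# field_y_mm: {_fmt(s.field_y_mm)}")
        lines.append(f"# ssd_mm: {_fmt(s.ssd_mm)}")
        lines.append(f"# scan_axis: {s.scan_axis}")
        if s.depth_mm is not None:
            lines.append(f"# depth_mm: {_fmt(s.depth_mm)}")
        if s.detector:
            lines.append(f"# detector: {s.detector}")
        if s.date:
            lines.append(f"# date: {s.date}")
        if s.comment:
            lines.append(f"# comment: {s.comment}")
        lines.append(_COLUMN_TITLE)
        for p, d in zip(curve.positions, curve.doses):
            lines.append(f"{_fmt(p)},{_fmt(d)}")
        lines.append("")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))
    return str(path)
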