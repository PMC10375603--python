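"""Lateral-profile parameter extraction.

All analyses run on a 0.1 mm grid resampled with a monotone (PCHIP)
interpolant — shape-preserving, no overshoot, and accurate enough at the
steep field edges for 0.01 mm-level crossing positions.  Flattened-beam
field edges are the 50%-of-CAX crossings.  Filter-free edges are found
in two stages: a coarse per-side extremum of the spline derivative of
2 mm-smoothed data (raw noisy derivatives are unusable), restricted to
the 20-80%-of-CAX dose corridor, then a parabola refinement of the
lightly-smoothed derivative magnitude around the coarse position (the
heavy smoothing of stage one would otherwise bias the extremum).
Nominal (header) field size — not the measured width — feeds the
unflatness offset, since the protocol offsets are nominal quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator
from scipy.ndimage import uniform_filter1d

from .beam_io import ScanCurve
from .errors import AnalysisError
from .synth_beams import unflatness_offset_mm

GRID_STEP_MM = 0.1
#: smoothing window for the coarse inflection search (FFF edges)
EDGE_SMOOTH_MM = 2.0
#: half-width of the parabola refinement around the coarse inflection
EDGE_REFINE_MM = 4.0
#: light smoothing applied to the data differentiated in the refinement
EDGE_REFINE_SMOOTH_MM = 1.0
#: smoothing for the central-region ratio metrics (flatness, symmetry);
#: both are max-statistics and would otherwise be biased upward by noise
CENTRAL_SMOOTH_MM = 2.0
#: narrower window for unflatness point reads: the FFF cone has a slope
#: discontinuity on-axis, which a wide average would bias low
UNFLATNESS_SMOOTH_MM = 1.0


def _require_profile(curve: ScanCurve) -> None:
    if not curve.is_profile:
        raise AnalysisError("expected a lateral profile curve")


def _resample(curve: ScanCurve, step: float = GRID_STEP_MM) -> tuple[np.ndarray, np.ndarray]:
    p = curve.positions
    n = int(round((p[-1] - p[0]) / step))
    grid = p[0] + step * np.arange(n + 1)
    return grid, np.clip(PchipInterpolator(p, curve.doses)(grid), 0.0, None)


def _box_filter(dose: np.ndarray, window_mm: float) -> np.ndarray:
    k = max(1, int(round(window_mm / GRID_STEP_MM)))
    if k % 2 == 0:
        k += 1
    return uniform_filter1d(dose, size=k, mode="nearest")


def smooth(curve: ScanCurve, window_mm: float) -> ScanCurve:
    """Centered moving average over ``window_mm`` on the 0.1 mm grid.

    A zero window is the identity (the input curve is returned as-is);
    constants are conserved exactly.
    """
    _require_profile(curve)
    if window_mm < 0:
        raise AnalysisError("smoothing window must be >= 0")
    if window_mm == 0:
        return curve
    grid, dose = _resample(curve)
    smoothed = _box_filter(dose, window_mm)
    return ScanCurve(curve.spec, grid, np.clip(smoothed, 0.0, None))


def _cax_dose(grid: np.ndarray, dose: np.ndarray) -> float:
    if not (grid[0] <= 0.0 <= grid[-1]):
        raise AnalysisError("profile does not cover the central axis")
    return float(np.interp(0.0, grid, dose))


def _level_crossings(grid: np.ndarray, dose: np.ndarray, level: float) -> tuple[float, float]:
    """Leftmost rising and rightmost falling crossing of ``level``."""
    mask = dose >= level
    if not mask.any() or mask[0] or mask[-1]:
        raise AnalysisError("no field edge: level crossing missing in scan range")
    first = int(np.argmax(mask))
    last = int(dose.size - 1 - np.argmax(mask[::-1]))
    xl = grid[first - 1] + (level - dose[first - 1]) / (
        dose[first] - dose[first - 1]
    ) * (grid[first] - grid[first - 1])
    xr = grid[last] + (dose[last] - level) / (dose[last] - dose[last + 1]) * (
        grid[last + 1] - grid[last]
    )
    return float(xl), float(xr)


def cax_correction(curve: ScanCurve) -> tuple[ScanCurve, float]:
    """Translate the profile so the midpoint of its 50%-of-CAX edges
    sits at x = 0; returns (centered curve, applied shift in mm)."""
    _require_profile(curve)
    grid, dose = _resample(curve)
    half = 0.5 * _cax_dose(grid, dose)
    xl, xr = _level_crossings(grid, dose, half)
    mid = 0.5 * (xl + xr)
    shift = -mid
    return curve.with_positions(curve.positions + shift), shift


def field_edges(curve: ScanCurve, fff: bool = False) -> tuple[float, float]:
    """(left, right) field-edge positions of a centered profile.

    Flattened: interpolated 50%-of-CAX crossings.  Filter-free: per-side
    inflection points (derivative extrema of a spline on smoothed data,
    refined by a local parabola), searched in the 20-80% corridor.
    """
    _require_profile(curve)
    if not fff:
        grid, dose = _resample(curve)
        return _level_crossings(grid, dose, 0.5 * _cax_dose(grid, dose))

    grid, raw = _resample(curve)
    heavy = _box_filter(raw, EDGE_SMOOTH_MM)
    der_coarse = CubicSpline(grid, heavy)(grid, 1)
    dcax = _cax_dose(grid, heavy)
    corridor = (heavy >= 0.2 * dcax) & (heavy <= 0.8 * dcax)
    der_fine = CubicSpline(grid, _box_filter(raw, EDGE_REFINE_SMOOTH_MM))(grid, 1)
    edges = []
    for side_mask in (grid < 0, grid > 0):
        idx = np.flatnonzero(corridor & side_mask)
        if idx.size == 0:
            raise AnalysisError("no inflection point found in the 20-80% corridor")
        j = idx[int(np.argmax(np.abs(der_coarse[idx])))]
        x0 = float(grid[j])
        near = np.abs(grid - x0) <= EDGE_REFINE_MM
        mag = np.abs(der_fine[near])
        a, b, _ = np.polyfit(grid[near] - x0, mag, 2)
        if a < 0:
            x0 = float(np.clip(x0 - b / (2 * a), grid[near][0], grid[near][-1]))
        edges.append(x0)
    return edges[0], edges[1]


def field_size(curve: ScanCurve, fff: bool = False) -> float:
    """Edge-to-edge field width (mm)."""
    left, right = field_edges(curve, fff=fff)
    return right - left


def flatness(curve: ScanCurve, region: float = 0.8) -> float:
    """100 * Dmax/Dmin over the central ``region`` of the field size.

    IEC-style ratio definition for flattened beams; a perfectly flat top
    scores 100.00.
    """
    _require_profile(curve)
    grid, dose = _resample(curve)
    dose = _box_filter(dose, CENTRAL_SMOOTH_MM)
    fs = field_size(curve, fff=False)
    half_window = region * fs / 2
    sel = np.abs(grid) <= half_window
    if not sel.any():
        raise AnalysisError("empty flatness window")
    dmin = float(dose[sel].min())
    if dmin <= 0:
        raise AnalysisError("non-positive dose inside the flatness window")
    return 100.0 * float(dose[sel].max()) / dmin


def unflatness(curve: ScanCurve, nominal_field_mm: float | None = None) -> float:
    """D_CAX over the mean off-axis dose at the protocol offset.

    The offset is 60% of the half field size below 10x10 cm2 and 80% at
    or above it, computed from the nominal field size (header value by
    default).  Averaging the two sides removes left/right asymmetry
    sensitivity.
    """
    _require_profile(curve)
    if nominal_field_mm is None:
        nominal_field_mm = curve.spec.nominal_field_mm
    off = unflatness_offset_mm(nominal_field_mm)
    p = curve.positions
    if not (p[0] <= -off and off <= p[-1]):
        raise AnalysisError(
            f"unflatness offset {off} mm outside scan range [{p[0]}, {p[-1]}]"
        )
    grid, dose = _resample(curve)
    dose = _box_filter(dose, UNFLATNESS_SMOOTH_MM)
    d0 = float(np.interp(0.0, grid, dose))
    dm = 0.5 * (float(np.interp(off, grid, dose)) + float(np.interp(-off, grid, dose)))
    if dm <= 0:
        raise AnalysisError("non-positive off-axis dose")
    return d0 / dm


def symmetry(curve: ScanCurve, region: float = 0.8) -> float:
    """Worst point-pair ratio 100*max(D(x)/D(-x), D(-x)/D(x)) over the
    central ``region`` of the field size; >= 100 by construction."""
    _require_profile(curve)
    grid, dose = _resample(curve)
    dose = _box_filter(dose, CENTRAL_SMOOTH_MM)
    fs = field_size(curve, fff=False)
    xs = np.arange(GRID_STEP_MM, region * fs / 2 + GRID_STEP_MM / 2, GRID_STEP_MM)
    xs = xs[(xs <= grid[-1]) & (-xs >= grid[0])]
    if xs.size == 0:
        raise AnalysisError("empty symmetry region")
    dp = np.interp(xs, grid, dose)
    dm = np.interp(-xs, grid, dose)
    if np.any(dp <= 0) or np.any(dm <= 0):
        raise AnalysisError("non-positive dose inside the symmetry region")
    return 100.0 * float(np.maximum(dp / dm, dm / dp).max())


def renormalize_fff(curve: ScanCurve) -> ScanCurve:
    """Rescale a centered FFF profile so the mean dose at its two edge
    inflection points equals 50.0; inflection positions are unchanged
    (the operation is idempotent)."""
    _require_profile(curve)
    il, ir = field_edges(curve, fff=True)
    mean_edge = 0.5 * (curve.dose_at(il) + curve.dose_at(ir))
    if mean_edge <= 0:
        raise AnalysisError("non-positive dose at the inflection points")
    return curve.with_doses(curve.doses * (50.0 / mean_edge))


def penumbra(curve: ScanCurve, fff: bool = False) -> tuple[float, float, float]:
    """Per-side 80-20% widths and their mean (mm) for a centered profile.

    Flattened profiles are normalized to 100 at the CAX; filter-free
    profiles are first renormalized via their inflection points so the
    80/20 levels refer to the flattened-equivalent scale.
    """
    _require_profile(curve)
    if fff:
        work = renormalize_fff(curve)
        grid, dose = _resample(work)
    else:
        grid, dose = _resample(curve)
        dose = dose * (100.0 / _cax_dose(grid, dose))
    try:
        x20l, x20r = _level_crossings(grid, dose, 20.0)
        x80l, x80r = _level_crossings(grid, dose, 80.0)
    except AnalysisError as exc:
        raise AnalysisError(f"missing 80/20 penumbra crossings: {exc}") from exc
    left = x80l - x20l
    right = x20r - x80r
    if left <= 0 or right <= 0:
        raise AnalysisError("degenerate penumbra (non-positive width)")
    return left, right, 0.5 * (left + right)


@dataclass(frozen=True)
class ProfileMetrics:
    """Extracted lateral-profile parameters for one curve."""

    d_cax: float
    field_size_mm: float
    flatness_pct: float | None
    unflatness: float | None
    symmetry_pct: float
    penumbra_left_mm: float
    penumbra_right_mm: float
    penumbra_avg_mm: float
    cax_shift_mm: float
    inflection_left_mm: float | None = None
    inflection_right_mm: float | None = None

    def to_dict(self) -> dict:
        rnd = lambda v, k: None if v is None else round(v, k)
        return {
            "d_cax": rnd(self.d_cax, 2),
            "field_size_mm": rnd(self.field_size_mm, 2),
            "flatness_pct": rnd(self.flatness_pct, 2),
            "unflatness": rnd(self.unflatness, 3),
            "symmetry_pct": rnd(self.symmetry_pct, 2),
            "penumbra_left_mm": rnd(self.penumbra_left_mm, 2),
            "penumbra_right_mm": rnd(self.penumbra_right_mm, 2),
            "penumbra_avg_mm": rnd(self.penumbra_avg_mm, 2),
            "cax_shift_mm": rnd(self.cax_shift_mm, 2),
            "inflection_left_mm": rnd(self.inflection_left_mm, 2),
            "inflection_right_mm": rnd(self.inflection_right_mm, 2),
        }


def profile_metrics(curve: ScanCurve, fff: bool | None = None,
                    region: float = 0.8) -> ProfileMetrics:
    """Full parameter record for one profile (CAX-centered internally).

    ``fff`` defaults to the curve's header flag; it selects the edge
    definition (inflection vs 50% crossing) and flatness vs unflatness.
    """
    _require_profile(curve)
    if fff is None:
        fff = curve.spec.fff
    centered, shift = cax_correction(curve)
    grid, dose = _resample(centered)
    d_cax = _cax_dose(grid, dose)
    if fff:
        il, ir = field_edges(centered, fff=True)
        fs = ir - il
        unflat = unflatness(centered)
        flat = None
    else:
        il = ir = None
        fs = field_size(centered, fff=False)
        flat = flatness(centered, region)
        unflat = None
    left, right, avg = penumbra(centered, fff=fff)
    return ProfileMetrics(
        d_cax=d_cax,
        field_size_mm=fs,
        flatness_pct=flat,
        unflatness=unflat,
        symmetry_pct=symmetry(centered, region),
        penumbra_left_mm=left,
        penumbra_right_mm=right,
        penumbra_avg_mm=avg,
        cax_shift_mm=shift,
        inflection_left_mm=il,
        inflection_right_mm=ir,
    )
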