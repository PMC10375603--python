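"""Depth-dose parameter extraction.

All doses are expressed as percent of the interpolated curve maximum
and level crossings use linear interpolation between samples.

The apex (depth of maximum) is located by fitting the classic two-term
build-up/attenuation parameterization

    P(z) = A * (1 - exp(-beta*z)) * exp(-mu*z)

to the whole curve, which pools the information of every sample: the
maximum of a megavoltage depth-dose curve is so flat (curvature of
order 0.1%/mm^2) that local vertex rules cannot deliver sub-millimetre
depths from noisy 1 mm sampling.  When the parameterization does not
describe the data (relative fit RMS above ``APEX_FIT_MAX_RMS_PCT``) a
windowed quadratic vertex around the sample maximum is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .beam_io import ScanCurve
from .errors import AnalysisError

#: accept the parametric apex fit only below this relative RMS (% of max)
APEX_FIT_MAX_RMS_PCT = 1.0
#: dose drop (% of max) defining the fallback quadratic-vertex window
APEX_FALLBACK_DROP_PCT = 2.0


def _require_depth(curve: ScanCurve) -> None:
    if curve.is_profile:
        raise AnalysisError("expected a depth-axis curve")


def _buildup_model(z, amplitude, beta, mu):
    return amplitude * (1.0 - np.exp(-beta * z)) * np.exp(-mu * z)


def _fit_apex(z: np.ndarray, d: np.ndarray) -> tuple[float, float] | None:
    """(depth, dose) of the parametric-fit maximum, or None if the
    build-up/attenuation model does not describe the curve."""
    dmax_raw = float(d.max())
    tail = z > z[0] + 0.6 * (z[-1] - z[0])
    if np.count_nonzero(tail) >= 3 and np.all(d[tail] > 0):
        mu0 = -np.polyfit(z[tail], np.log(d[tail]), 1)[0]
        mu0 = float(np.clip(mu0, 1e-4, 0.05))
    else:
        mu0 = 5e-3
    beta0 = 3.0 / max(float(z[np.argmax(d)]), 1.0)
    try:
        popt, _ = curve_fit(
            _buildup_model, z, d, p0=(dmax_raw, beta0, mu0),
            bounds=([1e-9, 1e-3, 1e-5], [np.inf, 5.0, 0.1]), maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return None
    amplitude, beta, mu = popt
    rms_pct = 100.0 * float(
        np.sqrt(np.mean((_buildup_model(z, *popt) - d) ** 2))
    ) / dmax_raw
    if rms_pct > APEX_FIT_MAX_RMS_PCT:
        return None
    zmax = float(np.log1p(beta / mu) / beta)
    if not (z[0] < zmax < z[-1]):
        return None
    return zmax, float(_buildup_model(zmax, *popt))


def _vertex_apex(z: np.ndarray, d: np.ndarray) -> tuple[float, float]:
    """Quadratic vertex over the samples within APEX_FALLBACK_DROP_PCT
    of the sample maximum (contiguous around the argmax)."""
    i0 = int(np.argmax(d))
    level = d[i0] * (1.0 - APEX_FALLBACK_DROP_PCT / 100.0)
    j = i0
    while j > 0 and d[j - 1] >= level:
        j -= 1
    k = i0
    while k < d.size - 1 and d[k + 1] >= level:
        k += 1
    if k - j + 1 < 3:
        j, k = max(0, i0 - 1), min(d.size - 1, i0 + 1)
    zc = z[i0]
    a, b, c = np.polyfit(z[j : k + 1] - zc, d[j : k + 1], 2)
    if a >= 0:
        return float(z[i0]), float(d[i0])
    zv = float(np.clip(-b / (2 * a), z[j] - zc, z[k] - zc))
    return float(zv + zc), float(np.polyval([a, b, c], zv))


def _apex(curve: ScanCurve) -> tuple[float, float]:
    z, d = curve.positions, curve.doses
    if int(np.argmax(d)) in (0, d.size - 1):
        raise AnalysisError("truncated build-up region: maximum at curve boundary")
    fitted = _fit_apex(z, d)
    if fitted is not None:
        return fitted
    return _vertex_apex(z, d)


def normalize_pdd(curve: ScanCurve) -> ScanCurve:
    """Scale doses so the interpolated maximum equals 100.0 (%).

    Positions are unchanged; idempotent to floating precision.
    """
    _require_depth(curve)
    try:
        _, dmax_dose = _apex(curve)
    except AnalysisError:
        dmax_dose = float(curve.doses.max())
    if dmax_dose <= 0:
        raise AnalysisError("cannot normalize: non-positive maximum dose")
    return curve.with_doses(curve.doses * (100.0 / dmax_dose))


def find_dmax(curve: ScanCurve) -> float:
    """Depth of maximum dose (mm), reported to 0.01 mm.

    Raises :class:`AnalysisError` when the sample maximum sits on the
    curve boundary (truncated build-up region).
    """
    _require_depth(curve)
    zv, _ = _apex(curve)
    return round(zv, 2)


def pdd_at_depth(curve: ScanCurve, depth_mm: float) -> float:
    """Dose at ``depth_mm`` as percent of the interpolated maximum."""
    _require_depth(curve)
    z = curve.positions
    if not (z[0] <= depth_mm <= z[-1]):
        raise AnalysisError(
            f"depth {depth_mm} mm outside sampled range [{z[0]}, {z[-1]}] mm"
        )
    norm = normalize_pdd(curve)
    return float(np.interp(depth_mm, norm.positions, norm.doses))


def r80(curve: ScanCurve) -> float:
    """Therapeutic range: depth beyond d_max where the PDD crosses 80%."""
    _require_depth(curve)
    norm = normalize_pdd(curve)
    dmax = find_dmax(curve)
    z, d = norm.positions, norm.doses
    beyond = np.flatnonzero((z > dmax) & (d < 80.0))
    if beyond.size == 0:
        raise AnalysisError("no 80% crossing beyond d_max within the scan range")
    k = int(beyond[0])
    if k == 0:
        raise AnalysisError("no 80% crossing beyond d_max within the scan range")
    z0, z1 = z[k - 1], z[k]
    d0, d1 = d[k - 1], d[k]
    return float(z0 + (d0 - 80.0) / (d0 - d1) * (z1 - z0))


def quality_index(curve: ScanCurve) -> float:
    """Q_i = 1.2661 * (PDD20/PDD10) - 0.0595 (TPR20,10 approximation)."""
    _require_depth(curve)
    if curve.positions[-1] < 200.0 or curve.positions[0] > 100.0:
        raise AnalysisError("quality index requires a curve spanning >= 200 mm")
    p10 = pdd_at_depth(curve, 100.0)
    p20 = pdd_at_depth(curve, 200.0)
    return 1.2661 * (p20 / p10) - 0.0595


def plateau_extent(curve: ScanCurve, tol_pct: float) -> float:
    """Width (mm) of the maximal contiguous interval containing d_max
    where the normalized dose stays >= 100 - tol_pct."""
    _require_depth(curve)
    if tol_pct < 0:
        raise AnalysisError("tol_pct must be >= 0")
    norm = normalize_pdd(curve)
    z, d = norm.positions, norm.doses
    # relative to the sample maximum: the fitted apex can sit slightly
    # above every sample, which would empty the interval at small tol
    level = float(d.max()) * (1.0 - tol_pct / 100.0)
    i0 = int(np.argmax(d))
    if d[i0] < level:
        return 0.0
    j = i0
    while j > 0 and d[j - 1] >= level:
        j -= 1
    k = i0
    while k < d.size - 1 and d[k + 1] >= level:
        k += 1
    if j == 0:
        left = float(z[0])
    else:
        left = float(z[j] - (d[j] - level) / (d[j] - d[j - 1]) * (z[j] - z[j - 1]))
    if k == d.size - 1:
        right = float(z[-1])
    else:
        right = float(z[k] + (d[k] - level) / (d[k] - d[k + 1]) * (z[k + 1] - z[k]))
    return right - left


@dataclass(frozen=True)
class PDDMetrics:
    """Extracted depth-dose parameters for one curve."""

    dmax_mm: float
    pdd10_pct: float
    pdd20_pct: float | None
    r80_mm: float
    quality_index: float | None
    plateau_mm: float
    plateau_tol_pct: float

    def to_dict(self) -> dict:
        out = {
            "dmax_mm": round(self.dmax_mm, 2),
            "pdd10_pct": round(self.pdd10_pct, 2),
            "pdd20_pct": None if self.pdd20_pct is None else round(self.pdd20_pct, 2),
            "r80_mm": round(self.r80_mm, 2),
            "quality_index": (
                None if self.quality_index is None else round(self.quality_index, 3)
            ),
            "plateau_mm": round(self.plateau_mm, 2),
            "plateau_tol_pct": self.plateau_tol_pct,
        }
        return out


def pdd_metrics(curve: ScanCurve, plateau_tol_pct: float = 0.5) -> PDDMetrics:
    """Extract the full depth-dose parameter record for one curve."""
    _require_depth(curve)
    has_200 = curve.positions[-1] >= 200.0 and curve.positions[0] <= 100.0
    return PDDMetrics(
        dmax_mm=find_dmax(curve),
        pdd10_pct=pdd_at_depth(curve, 100.0),
        pdd20_pct=pdd_at_depth(curve, 200.0) if has_200 else None,
        r80_mm=r80(curve),
        quality_index=quality_index(curve) if has_200 else None,
        plateau_mm=plateau_extent(curve, plateau_tol_pct),
        plateau_tol_pct=plateau_tol_pct,
    )
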