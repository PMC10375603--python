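"""1D gamma-index comparison of a measured curve against a baseline.

For every evaluated-curve sample above the dose threshold

    gamma(r) = min over r' in [r - 3*DTA, r + 3*DTA] of
               sqrt(((r' - r)/DTA)^2 + ((D_ref(r') - D_eval(r)) / dd_abs)^2)

with dd_abs = dd_pct/100 times the normalization dose (global reference
maximum by default).  The reference is treated as a piecewise-linear
curve, on which the minimizer has a closed form per segment, so gamma
values are exact rather than limited by a search-grid resolution.  A
point passes when gamma <= 1.  The evaluated curve is never resampled:
failures are counted sample by sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .beam_io import ScanCurve
from .errors import AnalysisError, ValidationError

_WINDOW_DTA = 3.0


@dataclass(frozen=True)
class GammaCriteria:
    """Dose-difference (% of normalization dose) / DTA (mm) criteria."""

    dd_pct: float
    dta_mm: float
    norm: str = "global_max"
    threshold_pct: float = 0.0

    def __post_init__(self) -> None:
        if not self.dd_pct > 0:
            raise ValidationError("dd_pct must be > 0")
        if not self.dta_mm > 0:
            raise ValidationError("dta_mm must be > 0")
        if self.norm not in ("global_max", "cax"):
            raise ValidationError("norm must be 'global_max' or 'cax'")
        if not (0 <= self.threshold_pct < 100):
            raise ValidationError("threshold_pct must be in [0, 100)")

    def scaled(self, k: float) -> "GammaCriteria":
        return GammaCriteria(self.dd_pct * k, self.dta_mm * k, self.norm,
                             self.threshold_pct)


@dataclass(frozen=True)
class GammaResult:
    """Per-point gamma values and the resulting pass rate."""

    positions: np.ndarray
    gamma_values: np.ndarray
    evaluated_n: int
    passed_n: int
    criteria: GammaCriteria

    def __post_init__(self) -> None:
        if self.passed_n > self.evaluated_n:
            raise ValidationError("passed_n cannot exceed evaluated_n")
        if self.evaluated_n != self.gamma_values.size:
            raise ValidationError("evaluated_n inconsistent with gamma_values")

    @property
    def pass_rate_pct(self) -> float:
        if self.evaluated_n == 0:
            raise AnalysisError("no evaluated points")
        return 100.0 * self.passed_n / self.evaluated_n

    @property
    def fully_passing(self) -> bool:
        return self.passed_n == self.evaluated_n


def _gamma_exact(rp: np.ndarray, rd: np.ndarray, pos: np.ndarray,
                 dose: np.ndarray, dta: float, dd_abs: float) -> np.ndarray:
    """Exact per-point gamma against the piecewise-linear reference.

    On each linear segment D(t) = m*t + q the squared gamma
    ((t-r)/dta)^2 + ((m*t + q - D)/dd_abs)^2 is a convex parabola whose
    stationary point is closed-form; clamping it into the segment (and
    into the +-3*DTA window) gives the segment minimum exactly.
    """
    out = np.empty(pos.size)
    seg_m = np.diff(rd) / np.diff(rp)
    for i, (r, d_eval) in enumerate(zip(pos, dose)):
        lo, hi = max(rp[0], r - _WINDOW_DTA * dta), min(rp[-1], r + _WINDOW_DTA * dta)
        j0 = max(0, int(np.searchsorted(rp, lo, side="right")) - 1)
        j1 = min(rp.size - 2, int(np.searchsorted(rp, hi, side="left")) - 1)
        segs = np.arange(j0, j1 + 1)
        m = seg_m[segs]
        q = rd[segs] - m * rp[segs]
        a = 1.0 / dta**2 + (m / dd_abs) ** 2
        b = -r / dta**2 + m * (q - d_eval) / dd_abs**2
        t = np.clip(-b / a, np.maximum(rp[segs], lo), np.minimum(rp[segs + 1], hi))
        g2 = ((t - r) / dta) ** 2 + ((m * t + q - d_eval) / dd_abs) ** 2
        out[i] = np.sqrt(g2.min())
    return out


def gamma_curve(reference: ScanCurve, evaluated: ScanCurve,
                criteria: GammaCriteria) -> GammaResult:
    """Gamma analysis of ``evaluated`` against ``reference``.

    Both curves must be of the same axis type, share an overlapping
    position range and already sit on a common dose scale.
    """
    if reference.is_profile != evaluated.is_profile:
        raise AnalysisError("curve axis types differ (profile vs depth)")
    rp, rd = reference.positions, reference.doses
    ep, ed = evaluated.positions, evaluated.doses
    if rp.size < 2:
        raise AnalysisError("reference curve needs at least 2 points")
    if max(rp[0], ep[0]) >= min(rp[-1], ep[-1]):
        raise AnalysisError("disjoint position ranges")

    if criteria.norm == "global_max":
        dnorm = float(rd.max())
    else:
        if not (rp[0] <= 0.0 <= rp[-1]):
            raise AnalysisError("cax normalization requires the reference to cover x=0")
        dnorm = float(np.interp(0.0, rp, rd))
    if dnorm <= 0:
        raise AnalysisError("non-positive normalization dose")
    dd_abs = criteria.dd_pct / 100.0 * dnorm

    dta = criteria.dta_mm
    sel = (ep >= rp[0]) & (ep <= rp[-1]) & (ed >= criteria.threshold_pct / 100.0 * dnorm)
    pos = ep[sel]
    dose = ed[sel]
    if pos.size == 0:
        raise AnalysisError("no evaluated points above threshold inside the reference range")

    gamma = _gamma_exact(rp, rd, pos, dose, dta, dd_abs)

    passed = int(np.count_nonzero(gamma <= 1.0))
    return GammaResult(
        positions=pos,
        gamma_values=gamma,
        evaluated_n=int(pos.size),
        passed_n=passed,
        criteria=criteria,
    )


@dataclass(frozen=True)
class BatchGammaSummary:
    n_curves: int
    n_fully_passing: int
    fully_passing_pct: float

    def to_dict(self) -> dict:
        return {
            "n_curves": self.n_curves,
            "n_fully_passing": self.n_fully_passing,
            "fully_passing_pct": self.fully_passing_pct,
        }


def batch_gamma(pairs: Sequence[tuple[ScanCurve, ScanCurve]],
                criteria: GammaCriteria) -> tuple[list[GammaResult], BatchGammaSummary]:
    """Gamma analysis of many (reference, evaluated) pairs.

    The summary reports how many curves pass at every point and the
    fraction of fully passing curves (percent, 2 decimals).
    """
    if not pairs:
        raise AnalysisError("empty pair list")
    results: list[GammaResult] = []
    for i, (ref, ev) in enumerate(pairs):
        try:
            results.append(gamma_curve(ref, ev, criteria))
        except (AnalysisError, ValidationError) as exc:
            raise AnalysisError(f"pair {i}: {exc}") from exc
    n_full = sum(1 for r in results if r.fully_passing)
    summary = BatchGammaSummary(
        n_curves=len(results),
        n_fully_passing=n_full,
        fully_passing_pct=round(100.0 * n_full / len(results), 2),
    )
    return results, summary
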