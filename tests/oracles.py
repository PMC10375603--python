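"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package implementations: the
gamma oracle scans a dense grid instead of minimizing analytically, and
the profile oracles use plain linear interpolation of the raw samples.
"""

from __future__ import annotations

import numpy as np


def brute_gamma(ref_pos, ref_dose, ev_pos, ev_dose, dd_pct, dta_mm,
                step_mm=1e-4, window_dta=3.0):
    """Dense-grid gamma of each evaluated sample inside the reference range."""
    rp = np.asarray(ref_pos, float)
    rd = np.asarray(ref_dose, float)
    dnorm = rd.max()
    dd_abs = dd_pct / 100.0 * dnorm
    out = []
    for r, d in zip(np.asarray(ev_pos, float), np.asarray(ev_dose, float)):
        if not (rp[0] <= r <= rp[-1]):
            continue
        grid = np.arange(r - window_dta * dta_mm, r + window_dta * dta_mm + step_mm / 2,
                         step_mm)
        grid = grid[(grid >= rp[0]) & (grid <= rp[-1])]
        dref = np.interp(grid, rp, rd)
        g = np.sqrt(((grid - r) / dta_mm) ** 2 + ((dref - d) / dd_abs) ** 2)
        out.append(float(g.min()))
    return np.array(out)


def brute_symmetry(positions, doses, field_size_mm, region=0.8, step_mm=0.01):
    """Point-wise folded max ratio on a dense linear-interp grid."""
    xs = np.arange(step_mm, region * field_size_mm / 2 + step_mm / 2, step_mm)
    dp = np.interp(xs, positions, doses)
    dm = np.interp(-xs, positions, doses)
    return 100.0 * float(np.maximum(dp / dm, dm / dp).max())


def bisect_level(fun, level, lo, hi, tol=1e-6):
    """Plain bisection for fun(x) == level, assuming one sign change."""
    flo = fun(lo) - level
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = fun(mid) - level
        if abs(hi - lo) < tol:
            return mid
        if (fm > 0) == (flo > 0):
            lo, flo = mid, fm
        else:
            hi = mid
    return 0.5 * (lo + hi)
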