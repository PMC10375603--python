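"""Synthetic water-phantom curves with closed-form ground truth.

Depth-dose model
    P(z) = (1 - exp(-beta*z)) * exp(-mu*z)
with analytic depth of maximum  z* = ln(1 + beta/mu) / beta.

Lateral profile model
    D(x) = 50 * [erf((F/2 - x)/(sigma*sqrt(2))) + erf((F/2 + x)/(sigma*sqrt(2)))]
           * g(x) * t(x)
with a piecewise-linear filter-free cone g(x) = 1 - c*|x| (c = 0 for a
flattened beam), a linear tilt t(x) = 1 + a*x/(F/2) modelling asymmetry,
an optional rigid shift of the beam axis and seeded Gaussian noise
relative to the curve maximum.

Ground-truth metrics are derived either in closed form or on a 0.01 mm
dense grid of the analytic model — always an order of magnitude finer
than any analysis grid, so they can serve as independent oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf

from .beam_io import BeamSpec, ScanCurve, ScanSet
from .errors import ValidationError

_SQRT2 = math.sqrt(2.0)
#: 80-20% width of a pure erf edge in units of sigma: 2 * Phi^-1(0.8)
ERF_PENUMBRA_PER_SIGMA = 1.6832424671458288
_DENSE_STEP = 0.01


# --------------------------------------------------------------------------
# parameter records
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthPDDParams:
    beta_per_mm: float = 0.25
    mu_per_mm: float = 0.005
    depth_range_mm: float = 300.0
    step_mm: float = 1.0
    noise_sd_pct: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.beta_per_mm > self.mu_per_mm > 0):
            raise ValidationError("require beta > mu > 0")
        if not self.step_mm > 0:
            raise ValidationError("step_mm must be > 0")
        if not self.depth_range_mm >= 10 * self.step_mm:
            raise ValidationError("depth_range_mm too short for the step")
        if self.noise_sd_pct < 0:
            raise ValidationError("noise_sd_pct must be >= 0")


@dataclass(frozen=True)
class SynthProfileParams:
    field_mm: float = 100.0
    sigma_mm: float = 4.0
    cone_slope_per_mm: float = 0.0
    tilt_fraction: float = 0.0
    shift_mm: float = 0.0
    step_mm: float = 2.0
    penumbra_step_mm: float = 1.0
    span_mm: float | None = None
    depth_mm: float = 100.0
    noise_sd_pct: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.field_mm > 6 * self.sigma_mm:
            raise ValidationError("require field_mm > 6*sigma_mm")
        if self.cone_slope_per_mm < 0 or self.cone_slope_per_mm * self.field_mm / 2 >= 1:
            raise ValidationError("require 0 <= cone_slope * field/2 < 1")
        if abs(self.tilt_fraction) >= 0.05:
            raise ValidationError("require |tilt_fraction| < 0.05")
        if not (self.step_mm > 0 and self.penumbra_step_mm > 0):
            raise ValidationError("steps must be > 0")
        if self.noise_sd_pct < 0:
            raise ValidationError("noise_sd_pct must be >= 0")

    @property
    def fff(self) -> bool:
        return self.cone_slope_per_mm > 0

    @property
    def effective_span_mm(self) -> float:
        return self.span_mm if self.span_mm is not None else self.field_mm + 80.0


@dataclass(frozen=True)
class GroundTruth:
    """Reference metric values for a generated curve.

    ``derivation`` records how each value was obtained:
    ``closed_form`` or ``dense_grid``.
    """

    values: Mapping[str, float]
    derivation: Mapping[str, str]

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def __contains__(self, key: str) -> bool:
        return key in self.values


# --------------------------------------------------------------------------
# analytic models
# --------------------------------------------------------------------------

def pdd_model(z, beta: float, mu: float):
    z = np.asarray(z, dtype=float)
    return (1.0 - np.exp(-beta * z)) * np.exp(-mu * z)


def pdd_dmax(beta: float, mu: float) -> float:
    """Closed-form depth of maximum of the depth-dose model."""
    return math.log1p(beta / mu) / beta


def profile_model(x, params: SynthProfileParams):
    x = np.asarray(x, dtype=float)
    F, s = params.field_mm, params.sigma_mm
    edge = 0.5 * (
        erf((F / 2 - x) / (s * _SQRT2)) + erf((F / 2 + x) / (s * _SQRT2))
    )
    cone = 1.0 - params.cone_slope_per_mm * np.abs(x)
    tilt = 1.0 + params.tilt_fraction * x / (F / 2)
    return 100.0 * edge * cone * tilt


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def _default_spec(machine_id: str, fff: bool, field_mm: float, scan_axis: str,
                  depth_mm: float | None) -> BeamSpec:
    return BeamSpec(
        machine_id=machine_id,
        energy_MV=6.0,
        fff=fff,
        field_x_mm=field_mm,
        field_y_mm=field_mm,
        ssd_mm=900.0,
        scan_axis=scan_axis,
        depth_mm=depth_mm,
        detector="synthetic",
    )


def make_pdd(params: SynthPDDParams, machine_id: str = "SYN",
             fff: bool = False, field_mm: float = 100.0) -> tuple[ScanCurve, GroundTruth]:
    """Generate a depth-dose curve plus its analytic ground truth."""
    b, m = params.beta_per_mm, params.mu_per_mm
    n = int(round(params.depth_range_mm / params.step_mm))
    z = params.step_mm * np.arange(n + 1)
    zmax = pdd_dmax(b, m)
    pmax = float(pdd_model(zmax, b, m))
    dose = 100.0 * pdd_model(z, b, m) / pmax
    if params.noise_sd_pct > 0:
        rng = np.random.default_rng(params.seed)
        dose = dose + rng.normal(0.0, params.noise_sd_pct, dose.size)
        dose = np.clip(dose, 0.0, None)

    pdd10 = 100.0 * float(pdd_model(100.0, b, m)) / pmax
    pdd20 = 100.0 * float(pdd_model(200.0, b, m)) / pmax
    r80_mm = brentq(
        lambda zz: float(pdd_model(zz, b, m)) - 0.8 * pmax,
        zmax, max(params.depth_range_mm, 10.0 / m), xtol=1e-6,
    )
    truth = GroundTruth(
        values={
            "dmax_mm": zmax,
            "pdd10_pct": pdd10,
            "pdd20_pct": pdd20,
            "r80_mm": float(r80_mm),
            "quality_index": 1.2661 * (pdd20 / pdd10) - 0.0595,
        },
        derivation={
            "dmax_mm": "closed_form",
            "pdd10_pct": "closed_form",
            "pdd20_pct": "closed_form",
            "r80_mm": "dense_grid",
            "quality_index": "closed_form",
        },
    )
    spec = _default_spec(machine_id, fff, field_mm, "depth", None)
    return ScanCurve(spec, z, dose), truth


def _profile_grid(params: SynthProfileParams) -> np.ndarray:
    """2 mm sampling in the central/out-of-field region, 1 mm (or the
    configured fine step) within +-4 sigma of either nominal field edge."""
    fine = params.penumbra_step_mm
    half = round((params.effective_span_mm / 2) / fine) * fine
    k = np.arange(-int(round(half / fine)), int(round(half / fine)) + 1)
    x = k * fine
    near_edge = np.abs(np.abs(x) - params.field_mm / 2) <= 4 * params.sigma_mm + fine
    on_coarse = np.isclose(
        x, np.round(x / params.step_mm) * params.step_mm, atol=1e-9
    )
    return x[near_edge | on_coarse]


def _inflection_points(params: SynthProfileParams) -> tuple[float, float]:
    """Per-side extremum of the model derivative within the 20-80%
    of-CAX dose corridor, on a dense grid of the analytic model."""
    half = params.effective_span_mm / 2
    x = np.arange(-half, half + _DENSE_STEP / 2, _DENSE_STEP)
    d = profile_model(x, params)
    dcax = float(profile_model(0.0, params))
    der = np.gradient(d, x)
    corridor = (d >= 0.2 * dcax) & (d <= 0.8 * dcax)
    out = []
    for side in (x < 0, x > 0):
        mask = corridor & side
        if not mask.any():
            raise ValidationError("no inflection corridor for these parameters")
        idx = np.flatnonzero(mask)
        out.append(float(x[idx[np.argmax(np.abs(der[idx]))]]))
    return out[0], out[1]


def _dense_field_and_penumbra(params: SynthProfileParams) -> dict[str, float]:
    """Field size and per-side 80-20 penumbra from the analytic model."""
    dcax = float(profile_model(0.0, params))
    half = params.effective_span_mm / 2

    def level_cross(level: float, lo: float, hi: float) -> float:
        return float(brentq(
            lambda xx: float(profile_model(xx, params)) - level, lo, hi, xtol=1e-8
        ))

    if params.fff:
        il, ir = _inflection_points(params)
        scale = 50.0 / (0.5 * (float(profile_model(il, params))
                               + float(profile_model(ir, params))))
        fs = ir - il
        # 80/20 crossings of the renormalized model near each edge
        def scaled_cross(level, lo, hi):
            return float(brentq(
                lambda xx: scale * float(profile_model(xx, params)) - level,
                lo, hi, xtol=1e-8,
            ))
        # left edge: dose rises with x, so x(20) < x(80)
        x20l = scaled_cross(20.0, -half, -params.field_mm / 2 + 1e-6)
        x80l = scaled_cross(80.0, -half, 0.0)
        x80r = scaled_cross(80.0, 0.0, half)
        x20r = scaled_cross(20.0, params.field_mm / 2 - 1e-6, half)
        pen_l = x80l - x20l
        pen_r = x20r - x80r
    else:
        fs_l = level_cross(0.5 * dcax, -half, 0.0)
        fs_r = level_cross(0.5 * dcax, 0.0, half)
        fs = fs_r - fs_l
        scale = 100.0 / dcax
        def scaled_cross(level, lo, hi):
            return float(brentq(
                lambda xx: scale * float(profile_model(xx, params)) - level,
                lo, hi, xtol=1e-8,
            ))
        x20l = scaled_cross(20.0, -half, -params.field_mm / 2 + 1e-6)
        x80l = scaled_cross(80.0, -half, 0.0)
        x80r = scaled_cross(80.0, 0.0, half)
        x20r = scaled_cross(20.0, params.field_mm / 2 - 1e-6, half)
        pen_l = x80l - x20l
        pen_r = x20r - x80r
    return {
        "field_size_mm": fs,
        "penumbra_left_mm": pen_l,
        "penumbra_right_mm": pen_r,
        "penumbra_mm": 0.5 * (pen_l + pen_r),
    }


def unflatness_offset_mm(nominal_field_mm: float) -> float:
    """Off-axis evaluation offset: half field size times 60% below the
    10x10 cm2 reference field, times 80% at or above it."""
    frac = 0.6 if nominal_field_mm < 100.0 else 0.8
    return nominal_field_mm / 2 * frac


def _truth_unflatness(params: SynthProfileParams) -> float:
    off = unflatness_offset_mm(params.field_mm)
    d0 = float(profile_model(0.0, params))
    dm = 0.5 * (float(profile_model(off, params)) + float(profile_model(-off, params)))
    return d0 / dm


def _truth_symmetry(params: SynthProfileParams, field_size_mm: float,
                    region: float = 0.8) -> float:
    xs = np.arange(_DENSE_STEP, region * field_size_mm / 2 + _DENSE_STEP / 2,
                   _DENSE_STEP)
    dp = profile_model(xs, params)
    dm = profile_model(-xs, params)
    ratio = np.maximum(dp / dm, dm / dp)
    return 100.0 * float(ratio.max())


def make_profile(params: SynthProfileParams,
                 machine_id: str = "SYN") -> tuple[ScanCurve, GroundTruth]:
    """Generate a lateral profile plus ground truth.

    The returned curve is sampled on the mixed 2 mm / 1 mm grid, shifted
    by ``shift_mm`` and noised per ``noise_sd_pct`` (relative to the
    curve maximum, seeded).  Truth values describe the unshifted,
    noise-free analytic model.
    """
    x = _profile_grid(params)
    dose = profile_model(x - params.shift_mm, params)
    if params.noise_sd_pct > 0:
        rng = np.random.default_rng(params.seed)
        dose = dose + rng.normal(
            0.0, params.noise_sd_pct / 100.0 * dose.max(), dose.size
        )
        dose = np.clip(dose, 0.0, None)

    geom = _dense_field_and_penumbra(params)
    closed_geometry = not params.fff and params.tilt_fraction == 0.0
    values = {
        "field_size_mm": geom["field_size_mm"],
        "penumbra_left_mm": geom["penumbra_left_mm"],
        "penumbra_right_mm": geom["penumbra_right_mm"],
        "penumbra_mm": geom["penumbra_mm"],
        "unflatness": _truth_unflatness(params),
        "symmetry_pct": _truth_symmetry(params, geom["field_size_mm"]),
        "cax_shift_mm": params.shift_mm,
    }
    derivation = {
        "field_size_mm": "closed_form" if closed_geometry else "dense_grid",
        "penumbra_left_mm": "closed_form" if closed_geometry else "dense_grid",
        "penumbra_right_mm": "closed_form" if closed_geometry else "dense_grid",
        "penumbra_mm": "closed_form" if closed_geometry else "dense_grid",
        "unflatness": "closed_form",
        "symmetry_pct": "dense_grid",
        "cax_shift_mm": "closed_form",
    }
    if params.fff:
        il, ir = _inflection_points(params)
        values["inflection_left_mm"] = il
        values["inflection_right_mm"] = ir
        derivation["inflection_left_mm"] = "dense_grid"
        derivation["inflection_right_mm"] = "dense_grid"
    spec = _default_spec(machine_id, params.fff, params.field_mm, "crossplane",
                         params.depth_mm)
    return ScanCurve(spec, x, dose), GroundTruth(values, derivation)


# --------------------------------------------------------------------------
# matched cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MachinePerturbation:
    """Per-machine departure from the shared baseline beam."""

    machine_id: str
    dmax_shift_mm: float = 0.0
    penumbra_delta_mm: float = 0.0
    tilt_delta: float = 0.0


def _beta_for_dmax(target_dmax_mm: float, mu: float) -> float:
    return float(brentq(
        lambda b: pdd_dmax(b, mu) - target_dmax_mm, 1e-4, 5.0, xtol=1e-10
    ))


def make_matched_cohort(
    profile_base: SynthProfileParams,
    pdd_base: SynthPDDParams,
    perturbations: Sequence[MachinePerturbation],
    seed: int = 0,
    field_sizes_mm: Sequence[float] = (30.0, 50.0, 100.0),
) -> tuple[dict[str, ScanSet], dict[str, GroundTruth]]:
    """One ScanSet per virtual machine: shared baseline beam plus the
    per-machine perturbations, reproducibly seeded.

    Returns the scan sets and, per machine, the ground truth of its
    (perturbed) beam so verdict tests can check against construction.
    """
    if not perturbations:
        raise ValidationError("at least one machine perturbation required")
    scans: dict[str, ScanSet] = {}
    truths: dict[str, GroundTruth] = {}
    for i, pert in enumerate(perturbations):
        machine_seed = seed * 10007 + i * 101
        dmax = pdd_dmax(pdd_base.beta_per_mm, pdd_base.mu_per_mm) + pert.dmax_shift_mm
        pdd_params = replace(
            pdd_base,
            beta_per_mm=_beta_for_dmax(dmax, pdd_base.mu_per_mm),
            seed=machine_seed,
        )
        curves: list[ScanCurve] = []
        values: dict[str, float] = {}
        derivation: dict[str, str] = {}
        pdd_curve, pdd_truth = make_pdd(
            pdd_params, machine_id=pert.machine_id, fff=profile_base.fff
        )
        curves.append(pdd_curve)
        for k, v in pdd_truth.values.items():
            values[k] = v
            derivation[k] = pdd_truth.derivation[k]
        for j, F in enumerate(field_sizes_mm):
            prof_params = replace(
                profile_base,
                field_mm=F,
                sigma_mm=profile_base.sigma_mm
                + pert.penumbra_delta_mm / ERF_PENUMBRA_PER_SIGMA,
                tilt_fraction=profile_base.tilt_fraction + pert.tilt_delta,
                seed=machine_seed + 7 * (j + 1),
            )
            prof_curve, prof_truth = make_profile(
                prof_params, machine_id=pert.machine_id
            )
            curves.append(prof_curve)
            for k, v in prof_truth.values.items():
                values[f"{k}@{F:g}"] = v
                derivation[f"{k}@{F:g}"] = prof_truth.derivation[k]
        scans[pert.machine_id] = ScanSet(
            tuple(curves),
            provenance={"source": "synthetic cohort", "seed": machine_seed},
        )
        truths[pert.machine_id] = GroundTruth(values, derivation)
    return scans, truths
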