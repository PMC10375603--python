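# beamaudit

A dosimetric beam-matching audit toolkit for megavoltage photon beams.
It covers the full analysis chain used when verifying that several
linacs share one beam model:

- **beam_io** — plain-text scan-curve files (`# key: value` headers +
  `position_mm,dose` CSV blocks) with exact round-trip guarantees.
- **pdd_metrics** — depth-dose parameters: depth of maximum, PDD at
  arbitrary depth (PDD10/PDD20), R80 therapeutic range, quality index,
  plateau extent.
- **profile_metrics** — lateral-profile parameters for flattened and
  flattening-filter-free (FFF) beams: CAX centering, field edges
  (50% crossing or inflection point), flatness, unflatness, symmetry,
  80–20% penumbra with FFF inflection-point renormalization.
- **gamma1d** — 1D gamma analysis (dose-difference % / DTA mm) with an
  exact per-segment minimizer, per-point gamma values, pass rates and
  batch summaries.
- **output_factors** — field-size output factors with size-dependent
  tolerances (2% at or below 4×4 cm², 1% above).
- **audit_report** — deviation-from-baseline records, study/vendor
  tolerance verdicts, pass-rate aggregation, literature differencing,
  and JSON/CSV/Markdown report bundles.
- **synth_beams** — synthetic water-phantom curves (build-up ×
  attenuation PDD model; double-erf × cone × tilt profile model) with
  closed-form or dense-grid ground truth, including matched
  multi-machine cohorts with controlled perturbations.

## Command-line interface

The console script is `audit`:

```sh
# generate synthetic data (scan files + ground-truth JSON)
audit synth --preset fff-10x10 --seed 1 --out demo/
audit synth --preset cohort --seed 1 --out cohort/

# extract metrics
audit pdd demo/fff-10x10.scan
audit profile demo/fff-10x10.scan --json profiles.json

# 1D gamma between two scan files (pair by block order)
audit gamma ref.scan eval.scan --dd 1 --dta 1

# output factors from a field_mm,reading CSV
audit of readings.csv --reference-field 100

# full audit: measured scans vs a baseline, tolerance verdicts
audit report --scans cohort/ --baseline cohort/LINAC1.scan --out report/
```

`audit report` exits with status 2 when any study-level criterion
fails; tolerances and gamma criteria can be overridden with a YAML file
(`--config`), e.g.

```yaml
tolerances:
  symmetry: {mode: relative_pct, study: 0.5, vendor: 1.5}
gamma:
  study: {dd_pct: 1, dta_mm: 1}
psqa_action_pct: 95
```

## Scan file dialect

One curve per block, blocks separated by a blank line:

```
# machine_id: LINAC1
# energy_MV: 6
# fff: true
# field_x_mm: 100
# field_y_mm: 100
# ssd_mm: 900
# scan_axis: crossplane
# depth_mm: 100
position_mm,dose
-90,0.31
...
```

Mandatory keys: `machine_id`, `energy_MV`, `fff`, `field_x_mm`,
`field_y_mm`, `ssd_mm`, `scan_axis` (plus `depth_mm` for profiles).
Positions are millimetres; off-axis coordinates are signed (negative =
toward the gun in-plane / toward the A bank cross-plane).  Dose values
are stored exactly as measured — normalization is always an explicit
downstream operation.
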