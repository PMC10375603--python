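import numpy as np
import pytest

from beamaudit import (
    AnalysisError,
    ScanCurve,
    SynthProfileParams,
    cax_correction,
    field_edges,
    field_size,
    flatness,
    make_profile,
    penumbra,
    profile_metrics,
    renormalize_fff,
    smooth,
    symmetry,
    unflatness,
)
from beamaudit.synth_beams import unflatness_offset_mm

from .conftest import make_curve
from .oracles import brute_symmetry


def _centered(params):
    curve, truth = make_profile(params)
    centered, _ = cax_correction(curve)
    return centered, truth


class TestSmooth:
    def test_zero_window_identity(self, ff_profile):
        curve, _ = ff_profile
        assert smooth(curve, 0.0) is curve

    def test_constant_conserved(self, profile_spec):
        x = np.linspace(-80, 80, 161)
        curve = make_curve(profile_spec, x, np.full(161, 7.25))
        out = smooth(curve, 5.0)
        np.testing.assert_allclose(out.doses, 7.25, atol=1e-12)

    def test_noise_reduction(self):
        clean, _ = make_profile(SynthProfileParams())
        noisy, _ = make_profile(SynthProfileParams(noise_sd_pct=0.5, seed=3))
        sm = smooth(noisy, 2.0)
        ref = np.interp(sm.positions, clean.positions, clean.doses)
        raw = np.interp(noisy.positions, clean.positions, clean.doses)
        rms_smoothed = np.sqrt(np.mean((sm.doses - ref) ** 2))
        rms_raw = np.sqrt(np.mean((noisy.doses - raw) ** 2))
        assert rms_smoothed < rms_raw

    def test_negative_window(self, ff_profile):
        with pytest.raises(AnalysisError):
            smooth(ff_profile[0], -1.0)


class TestCaxCorrection:
    def test_translated_profile(self):
        curve, _ = make_profile(SynthProfileParams(shift_mm=1.0))
        centered, shift = cax_correction(curve)
        assert shift == pytest.approx(-1.0, abs=0.05)
        left, right = field_edges(centered)
        assert 0.5 * (left + right) == pytest.approx(0.0, abs=0.05)

    def test_already_centered(self, ff_profile):
        _, shift = cax_correction(ff_profile[0])
        assert shift == pytest.approx(0.0, abs=0.01)

    def test_single_edge_in_range(self, profile_spec):
        x = np.linspace(-5, 60, 66)
        dose = 100.0 * (x < 50)  # left edge out of scan range
        dose[dose == 0] = 1.0
        with pytest.raises(AnalysisError, match="edge"):
            cax_correction(make_curve(profile_spec, x, dose))


class TestFieldEdges:
    def test_ff_erf_edges(self, ff_profile):
        curve, _ = ff_profile
        left, right = field_edges(curve)
        assert left == pytest.approx(-50.0, abs=0.05)
        assert right == pytest.approx(50.0, abs=0.05)

    def test_fff_inflection_near_nominal_edge(self, fff_profile):
        curve, truth = fff_profile
        left, right = field_edges(curve, fff=True)
        assert left == pytest.approx(-50.0, abs=0.3)
        assert right == pytest.approx(50.0, abs=0.3)
        # against the dense-grid derivative oracle of the analytic model
        assert left == pytest.approx(truth["inflection_left_mm"], abs=0.1)
        assert right == pytest.approx(truth["inflection_right_mm"], abs=0.1)

    def test_flat_profile_no_edge(self, profile_spec):
        x = np.linspace(-80, 80, 161)
        with pytest.raises(AnalysisError, match="edge"):
            field_edges(make_curve(profile_spec, x, np.full(161, 50.0)))


class TestFieldSize:
    @pytest.mark.parametrize("F,sigma", [(100.0, 4.0), (30.0, 3.0)])
    def test_nominal_recovery(self, F, sigma):
        centered, truth = _centered(SynthProfileParams(field_mm=F, sigma_mm=sigma))
        assert field_size(centered) == pytest.approx(F, abs=0.1)
        assert field_size(centered) == pytest.approx(truth["field_size_mm"], abs=0.1)

    def test_tilt_leaves_size(self):
        base, _ = _centered(SynthProfileParams())
        tilted, truth = _centered(SynthProfileParams(tilt_fraction=0.01))
        assert field_size(tilted) == pytest.approx(field_size(base), abs=0.1)
        assert field_size(tilted) == pytest.approx(truth["field_size_mm"], abs=0.1)


class TestFlatness:
    def test_flat_top(self, profile_spec):
        x = np.linspace(-80, 80, 161)
        dose = np.where(np.abs(x) <= 55, 100.0, 1.0)
        assert flatness(make_curve(profile_spec, x, dose)) == pytest.approx(100.0, abs=0.01)

    def test_linear_tilt_closed_form(self):
        # 2% tilt across the central 80% window: 100*(1.01/0.99) = 102.02
        centered, _ = _centered(SynthProfileParams(sigma_mm=3.0, tilt_fraction=0.0125))
        assert flatness(centered) == pytest.approx(102.02, abs=0.1)

    def test_paper_scale_magnitude(self):
        # gentle dome, as measured at depth on a flattened beam
        centered, _ = _centered(SynthProfileParams(sigma_mm=3.0, cone_slope_per_mm=0.0006))
        assert 102.0 < flatness(centered) < 106.0


class TestUnflatness:
    def test_offset_rule(self):
        assert unflatness_offset_mm(100.0) == pytest.approx(40.0)
        assert unflatness_offset_mm(30.0) == pytest.approx(9.0)

    def test_flat_profile(self, profile_spec):
        x = np.linspace(-80, 80, 161)
        dose = np.where(np.abs(x) <= 55, 100.0, 1.0)
        curve = make_curve(profile_spec, x, dose)
        assert unflatness(curve) == pytest.approx(1.000, abs=1e-6)

    def test_cone_closed_form(self):
        # narrow edge (sigma=2) so the erf rolloff at 40 mm is negligible:
        # 1/(1 - 0.00322*40) = 1.148
        centered, _ = _centered(
            SynthProfileParams(sigma_mm=2.0, cone_slope_per_mm=0.00322)
        )
        assert unflatness(centered) == pytest.approx(1.148, abs=0.002)

    def test_against_truth(self, fff_profile):
        curve, truth = fff_profile
        centered, _ = cax_correction(curve)
        assert unflatness(centered) == pytest.approx(truth["unflatness"], abs=0.002)

    def test_offset_outside_range(self):
        params = SynthProfileParams(field_mm=100.0, span_mm=110.0, sigma_mm=4.0)
        curve, _ = make_profile(params)
        narrow = ScanCurve(curve.spec, curve.positions[np.abs(curve.positions) <= 35],
                           curve.doses[np.abs(curve.positions) <= 35])
        with pytest.raises(AnalysisError, match="offset"):
            unflatness(narrow)


class TestSymmetry:
    def test_mirror_symmetric(self, ff_profile):
        curve, _ = ff_profile
        assert symmetry(curve) == pytest.approx(100.00, abs=1e-6)

    def test_worst_point_pair(self, profile_spec):
        x = np.linspace(-80, 80, 161)
        dose = np.where(np.abs(x) <= 55, 100.0, 1.0)
        dose = np.where((x >= 20) & (x <= 30), 100.5, dose)  # 0.5% bump one side
        assert symmetry(make_curve(profile_spec, x, dose)) == pytest.approx(100.50, abs=0.02)

    def test_tilt_vs_brute_oracle(self):
        curve, _ = make_profile(SynthProfileParams(tilt_fraction=0.005))
        expect = brute_symmetry(curve.positions, curve.doses, 100.0)
        assert symmetry(curve) == pytest.approx(expect, abs=0.05)

    def test_mirror_invariance(self):
        curve, _ = make_profile(SynthProfileParams(tilt_fraction=0.004))
        mirrored = ScanCurve(curve.spec, -curve.positions[::-1], curve.doses[::-1])
        assert symmetry(mirrored) == pytest.approx(symmetry(curve), abs=1e-9)

    @pytest.mark.parametrize("tilt", [0.0, 0.002, -0.004, 0.01])
    def test_at_least_100(self, tilt):
        curve, _ = make_profile(SynthProfileParams(tilt_fraction=tilt))
        assert symmetry(curve) >= 100.0


class TestRenormalizeFFF:
    def test_inflection_dose_is_50(self, fff_profile):
        curve, _ = fff_profile
        out = renormalize_fff(curve)
        left, right = field_edges(out, fff=True)
        assert out.dose_at(left) == pytest.approx(50.0, abs=0.5)
        assert out.dose_at(right) == pytest.approx(50.0, abs=0.5)

    def test_zero_cone_limit_matches_cax_normalization(self):
        curve, _ = make_profile(SynthProfileParams(sigma_mm=4.0))
        out = renormalize_fff(curve)
        cax_scale = 100.0 / curve.dose_at(0.0)
        mid = curve.n // 2
        fff_scale = out.doses[mid] / curve.doses[mid]
        assert fff_scale == pytest.approx(cax_scale, rel=0.005)

    def test_idempotent(self, fff_profile):
        once = renormalize_fff(fff_profile[0])
        twice = renormalize_fff(once)
        np.testing.assert_allclose(twice.doses, once.doses, atol=1e-6)


class TestPenumbra:
    def test_erf_closed_form(self, ff_profile):
        curve, _ = ff_profile
        left, right, avg = penumbra(curve)
        assert left == pytest.approx(6.73, abs=0.05)
        assert right == pytest.approx(6.73, abs=0.05)
        assert avg == pytest.approx(1.6832424671 * 4.0, abs=0.05)

    def test_linear_in_sigma(self):
        curve, _ = make_profile(SynthProfileParams(sigma_mm=2.0))
        _, _, avg = penumbra(curve)
        assert avg == pytest.approx(3.37, abs=0.05)

    def test_fff_against_truth(self, fff_profile):
        curve, truth = fff_profile
        left, right, avg = penumbra(curve, fff=True)
        assert avg == pytest.approx(truth["penumbra_mm"], abs=0.05)

    def test_paper_scale_magnitude(self):
        # sigma ~4.5 lands in the published 6-8 mm penumbra range
        curve, _ = make_profile(SynthProfileParams(sigma_mm=4.5))
        _, _, avg = penumbra(curve)
        assert 6.0 < avg < 8.0

    def test_missing_crossings(self, profile_spec):
        x = np.linspace(-80, 80, 161)
        dose = np.clip(100.0 - np.abs(x), 30.0, None)  # never reaches 20%
        with pytest.raises(AnalysisError, match="penumbra"):
            penumbra(make_curve(profile_spec, x, dose))


class TestProfileMetricsRecord:
    def test_ff_record(self, ff_profile):
        curve, truth = ff_profile
        m = profile_metrics(curve)
        assert m.unflatness is None
        assert m.flatness_pct is not None
        assert m.field_size_mm == pytest.approx(truth["field_size_mm"], abs=0.1)
        assert m.penumbra_avg_mm == pytest.approx(truth["penumbra_mm"], abs=0.05)
        assert m.symmetry_pct >= 100.0

    def test_fff_record(self, fff_profile):
        curve, truth = fff_profile
        m = profile_metrics(curve)
        assert m.flatness_pct is None
        assert m.unflatness == pytest.approx(truth["unflatness"], abs=0.002)
        assert m.unflatness >= 1.0
        assert m.inflection_left_mm is not None
        assert m.penumbra_left_mm > 0 and m.penumbra_right_mm > 0

    def test_fff_flag_from_header(self, fff_profile):
        curve, _ = fff_profile
        assert curve.spec.fff
        m = profile_metrics(curve)  # no explicit flag
        assert m.unflatness is not None


class TestInvariants:
    def test_penumbra_increasing_in_sigma(self):
        widths = []
        for sigma in (2.0, 3.0, 4.0, 5.0):
            curve, _ = make_profile(SynthProfileParams(sigma_mm=sigma))
            widths.append(penumbra(curve)[2])
        assert np.all(np.diff(widths) > 0)

    def test_field_size_independent_of_sigma(self):
        sizes = [
            field_size(make_profile(SynthProfileParams(sigma_mm=s))[0])
            for s in (2.0, 4.0, 6.0, 8.0, 10.0)
        ]
        assert np.ptp(sizes) < 0.2

    def test_noise_free_recovery_against_truth_grid(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            F = float(rng.choice([50.0, 100.0]))
            params = SynthProfileParams(
                field_mm=F,
                sigma_mm=float(rng.uniform(2.5, 4.5)),
                cone_slope_per_mm=float(rng.choice([0.0, 0.003])),
                tilt_fraction=float(rng.uniform(-0.004, 0.004)),
            )
            curve, truth = make_profile(params)
            fff = params.fff
            left, right = field_edges(curve, fff=fff)
            assert right - left == pytest.approx(truth["field_size_mm"], abs=0.1)
            assert penumbra(curve, fff=fff)[2] == pytest.approx(
                truth["penumbra_mm"], abs=0.05
            )
            assert unflatness(curve) == pytest.approx(truth["unflatness"], abs=0.002)
            assert symmetry(curve) == pytest.approx(truth["symmetry_pct"], abs=0.05)
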