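import numpy as np
import pytest

from beamaudit import (
    BeamSpec,
    ScanCurve,
    SynthPDDParams,
    SynthProfileParams,
    make_pdd,
    make_profile,
)


@pytest.fixture
def profile_spec():
    return BeamSpec(
        machine_id="TEST",
        energy_MV=6.0,
        fff=False,
        field_x_mm=100.0,
        field_y_mm=100.0,
        ssd_mm=900.0,
        scan_axis="crossplane",
        depth_mm=100.0,
    )


@pytest.fixture
def depth_spec():
    return BeamSpec(
        machine_id="TEST",
        energy_MV=6.0,
        fff=False,
        field_x_mm=100.0,
        field_y_mm=100.0,
        ssd_mm=900.0,
        scan_axis="depth",
    )


@pytest.fixture
def default_pdd():
    """Noise-free depth-dose curve with its ground truth."""
    return make_pdd(SynthPDDParams())


@pytest.fixture
def ff_profile():
    """Noise-free flattened 10x10 profile with ground truth."""
    return make_profile(SynthProfileParams(field_mm=100.0, sigma_mm=4.0))


@pytest.fixture
def fff_profile():
    """Noise-free filter-free 10x10 profile with ground truth."""
    return make_profile(
        SynthProfileParams(field_mm=100.0, sigma_mm=4.0, cone_slope_per_mm=0.0032)
    )


def make_curve(spec, positions, doses):
    return ScanCurve(spec, np.asarray(positions, float), np.asarray(doses, float))
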