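import pytest

from tldose.calibration import CalibrationCurve
from tldose.dose import load_coefficients
from tldose.phantom import load_packaged_layout
from tldose.protocol import load_packaged_protocols


@pytest.fixture(scope="session")
def adult_layout():
    return load_packaged_layout("adult_rando")


@pytest.fixture(scope="session")
def pediatric_layout():
    return load_packaged_layout("pediatric_cirs")


@pytest.fixture(scope="session")
def adult_protocols():
    return load_packaged_protocols("adult")


@pytest.fixture(scope="session")
def pediatric_protocols():
    return load_packaged_protocols("pediatric")


@pytest.fixture(scope="session")
def coeffs_120():
    return load_coefficients(120)


@pytest.fixture(scope="session")
def coeffs_80():
    return load_coefficients(80)


@pytest.fixture
def exact_curve():
    """Noise-free calibration line used by inverse-consistency tests."""
    return CalibrationCurve(slope=0.002, intercept=0.0, beam_quality="CT-120kV")
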