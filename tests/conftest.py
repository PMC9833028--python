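import pytest

from mdmsim.chip import builtin_elisa_layout
from mdmsim.protocol import builtin_elisa_protocol


@pytest.fixture()
def layout():
    return builtin_elisa_layout()


@pytest.fixture()
def protocol():
    return builtin_elisa_protocol()


@pytest.fixture(scope="session")
def shared_calibration():
    """Render-derived calibration curve; expensive enough to share."""
    from mdmsim.workflow import calibration_from_renders

    return calibration_from_renders()
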