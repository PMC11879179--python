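import pytest

from tunaforage import (
    ModelParams,
    calibrate_detection,
    default_stages,
)


@pytest.fixture(scope="session")
def calibrated():
    """Default parameters with the detection constant solved from the anchor."""
    return calibrate_detection(ModelParams())


@pytest.fixture(scope="session")
def full_capture(calibrated):
    """Calibrated parameters with capture probability forced to 1."""
    return calibrated.with_(assume_full_capture=True)


@pytest.fixture(scope="session")
def stages():
    return {s.code: s for s in default_stages()}
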