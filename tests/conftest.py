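import pytest

from tkicea import calibrated_toggles, load_parameters


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def toggles():
    """Structural configuration selected by calibration (cached per process)."""
    return calibrated_toggles()
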