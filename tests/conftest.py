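import pytest

from epoca_model import derive_model_inputs, load_params


@pytest.fixture(scope="session")
def params():
    return load_params()


@pytest.fixture(scope="session")
def inputs(params):
    """Calibrated model inputs (mortality + occupancy corrections); shared
    across the suite because calibration runs the cohort engine."""
    return derive_model_inputs(params)
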