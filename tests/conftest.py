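import numpy as np
import pytest

from ebfilm import (
    CalibrationTruth,
    ScannerModel,
    example_source_model,
)


@pytest.fixture(scope="session")
def model():
    return example_source_model(0.0)


@pytest.fixture(scope="session")
def truth():
    return CalibrationTruth()


@pytest.fixture(scope="session")
def noiseless():
    return ScannerModel.noiseless()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture(scope="session")
def noiseless_calibration(truth, model, noiseless):
    """Per-channel curves fitted from a noiseless synthetic calibration run."""
    from ebfilm import run_calibration_study

    return run_calibration_study(
        seed=11, truth=truth, model=model, scanner=noiseless
    )


@pytest.fixture(scope="session")
def noisy_calibration(truth, model):
    from ebfilm import run_calibration_study

    return run_calibration_study(seed=11, truth=truth, model=model)
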