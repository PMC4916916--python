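import numpy as np
import pytest

from spectrum_effect import (
    MeasurementModel,
    calibrate_error_sd,
    scenario1_model,
)


@pytest.fixture(scope="session")
def pop20():
    """Single-normal population with 20% true prevalence (sd 1, threshold 7)."""
    return scenario1_model(0.20)


@pytest.fixture(scope="session")
def calibrated_sigma(pop20):
    """Error sd at which analytic specificity is exactly 95% for pop20."""
    return calibrate_error_sd(pop20, "specificity", 0.95)


@pytest.fixture(scope="session")
def calibrated_mm(calibrated_sigma):
    return MeasurementModel(error_sd=calibrated_sigma)


@pytest.fixture()
def rng():
    return np.random.default_rng(20160622)
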