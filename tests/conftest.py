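import numpy as np
import pytest

from activesepta import readout as R


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def light_model():
    return R.LightSpreadModel()


@pytest.fixture(scope="session")
def pixel_spec():
    return R.PixelArraySpec()


@pytest.fixture(scope="session")
def calibration(light_model, pixel_spec):
    """DOI calibration shared across readout/experiment tests."""
    return R.calibrate(light_model, pixel_spec, n_events=12_000, seed=424242)
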