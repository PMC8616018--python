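import numpy as np
import pytest

from bloodmir import BiofluidModel, load_water_table
from bloodmir.synth import default_grid


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def water():
    return load_water_table()


@pytest.fixture()
def clean_model():
    """Generator with every stochastic artifact switched off."""
    return BiofluidModel(noise_sd=0.0, baseline_drift=0.0, co2_artifact=0.0)


@pytest.fixture()
def noisy_model():
    return BiofluidModel(seed=7)


@pytest.fixture()
def toy_spectrum():
    """Small absorbance spectrum with signal-free endpoints."""
    from bloodmir import Spectrum

    nu = np.linspace(1000.0, 2000.0, 101)
    vals = 0.5 * np.exp(-((nu - 1500.0) / 60.0) ** 2)
    return Spectrum(nu, vals, "absorbance", {"sample": "toy"})
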