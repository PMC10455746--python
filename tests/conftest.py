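import numpy as np
import pytest

from scaffoldlab import synthetic_data as synth


@pytest.fixture
def noiseless_spectrum_model():
    """Full eight-band coated-scaffold spectrum, no baseline, no noise."""
    return synth.SpectrumModel(bands=synth.default_bands(), noise_sd=0.0, seed=0)


@pytest.fixture
def single_band_model():
    """One isolated apatite band (960 cm^-1, amplitude 100, sigma 8)."""
    return synth.SpectrumModel(
        bands=(synth.BandSpec("ha_960", 960.0, 100.0, 8.0),), noise_sd=0.0, seed=0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
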