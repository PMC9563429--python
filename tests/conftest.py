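import numpy as np
import pytest

from nirmeat import synth


@pytest.fixture(scope="session")
def small_grid():
    """64-channel wavelength grid spanning the modelling range."""
    return synth.default_wavelengths(64)


@pytest.fixture(scope="session")
def endmembers(small_grid):
    return synth.make_endmembers(wavelengths=small_grid)


@pytest.fixture(scope="session")
def small_dataset(endmembers):
    """Three replicates per configuration: 39 samples, 624 point spectra."""
    design = synth.DatasetDesign(replicates_per_config=3)
    return synth.generate_dataset(design, endmembers,
                                  synth.NOISE_PRESETS["low"], seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
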