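import numpy as np
import pytest

from mannoload import Band, SpectrumGroundTruth, TitrationGroundTruth


@pytest.fixture
def gaussian_spectrum():
    """A single Gaussian band (center 1650, width 25) on a flat baseline."""
    from mannoload import Spectrum

    nu = np.arange(900.0, 3000.5, 1.0)
    a = np.exp(-0.5 * ((nu - 1650.0) / 25.0) ** 2)
    return Spectrum(nu, a)


@pytest.fixture
def noiseless_titration_gt():
    return TitrationGroundTruth(noise_sd=0.0, seed=0)


@pytest.fixture
def single_band_gt():
    return SpectrumGroundTruth(
        bands=(Band(center=1650.0, width=25.0, height_free=1.0, height_bound=0.4),),
        noise_sd=0.0,
    )
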