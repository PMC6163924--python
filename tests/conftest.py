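import numpy as np
import pytest

from earlyvigor.synthetic import (
    TrialDesign,
    default_endmembers,
    generate_trial,
)


@pytest.fixture(scope="session")
def endmembers():
    return default_endmembers()


@pytest.fixture(scope="session")
def trial():
    """Default four-date trial without images (spectra + traits only)."""
    return generate_trial(TrialDesign(seed=1), render_images=False)


@pytest.fixture(scope="session")
def image_trial():
    """Four-date trial with small rendered quadrat images."""
    return generate_trial(TrialDesign(seed=2), image_size=96)


def make_spectrum(wavelengths, reflectance, **kw):
    from earlyvigor.spectra import Spectrum

    return Spectrum(np.asarray(wavelengths, float), np.asarray(reflectance, float), **kw)
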