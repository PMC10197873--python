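import numpy as np
import pytest

from sporesort import Spectrum, SpectrumMeta
from sporesort.synthetic_data import phenotype_preset


def noiseless_preset(tag: str) -> Spectrum:
    """Noiseless evaluation of a phenotype preset as a Spectrum."""
    model = phenotype_preset(tag)
    return Spectrum(
        model.wavenumbers(), model.evaluate(), SpectrumMeta(phenotype=model.phenotype)
    )


@pytest.fixture(scope="session")
def medium():
    return noiseless_preset("medium")


@pytest.fixture(scope="session")
def endospore():
    return noiseless_preset("endospore")


@pytest.fixture()
def flat_spectrum():
    w = np.arange(400.0, 3300.0, 3.5)
    return Spectrum(w, np.full(w.size, 5.0))
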