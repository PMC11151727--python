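import numpy as np
import pytest

from ftirfg.spectra import CANONICAL_GRID, Spectrum


@pytest.fixture
def grid():
    return np.asarray(CANONICAL_GRID)


def gaussian(wn, center, sigma, height):
    return height * np.exp(-0.5 * ((np.asarray(wn) - center) / sigma) ** 2)


@pytest.fixture
def make_spectrum():
    """Factory for spectra on the canonical grid from an absorbance array."""

    def _make(absorbance, stage="raw", sid="test", kind="sample"):
        return Spectrum(id=sid, wavenumbers=np.asarray(CANONICAL_GRID),
                        absorbance=np.asarray(absorbance, dtype=float),
                        stage=stage, filter_kind=kind)

    return _make
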