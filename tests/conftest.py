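import numpy as np
import pytest

import teanir as tn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spectra(rng):
    """30 samples x 12 positive bands on a toy wavenumber grid."""
    wn = np.linspace(4000.0, 4110.0, 12)
    return tn.SpectraSet(wn, rng.uniform(0.2, 1.0, (30, 12)))


@pytest.fixture(scope="session")
def easy_bundle():
    return tn.make_benchmark("easy", seed=7)


@pytest.fixture(scope="session")
def easy_dataset(easy_bundle):
    return tn.align(easy_bundle.spectra, easy_bundle.indicators, "soluble_sugar")
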