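import numpy as np
import pytest

from oxymap.spectra import (
    build_design_matrix,
    default_filter_bank,
    load_default_spectra,
)


@pytest.fixture(scope="session")
def bank():
    return default_filter_bank()


@pytest.fixture(scope="session")
def chromophores():
    return load_default_spectra()


@pytest.fixture(scope="session")
def design(bank, chromophores):
    return build_design_matrix(bank, chromophores)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
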