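import numpy as np
import pytest

from lsdpa import load_chromophore_table


@pytest.fixture(scope="session")
def table():
    return load_chromophore_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_normalized_spectra(n_rows, n_wl, rng):
    """Strictly positive sum-to-one rows (Dirichlet)."""
    return rng.dirichlet(np.ones(n_wl), size=n_rows)
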