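import numpy as np
import pytest

from prolspec import StudyDesign, rank_split, simulate_spectra_table
from prolspec.synth import make_endmembers


@pytest.fixture(scope="session")
def default_table():
    """Modelling table of the default synthetic study (100 x 350)."""
    return simulate_spectra_table(StudyDesign())


@pytest.fixture(scope="session")
def informative_indices(default_table):
    return make_endmembers(default_table.grid).informative_indices


@pytest.fixture(scope="session")
def default_split(default_table):
    cal, pred = rank_split(default_table.y)
    return cal, pred


@pytest.fixture(scope="session")
def planted_toy():
    """100 x 50 toy with 2 informative bands at SNR ~20, fixed seed.

    y depends linearly on the two planted bands; the remaining 48 bands are
    pure noise.  Returns (X, y, informative_indices).
    """
    rng = np.random.default_rng(7)
    n, p = 100, 50
    informative = np.array([11, 37])
    signal = rng.normal(0.0, 1.0, n)
    X = rng.normal(0.0, 1.0, (n, p))
    for j in informative:
        X[:, j] = signal + rng.normal(0.0, 0.05, n)  # SNR 20 on planted bands
    y = 2.0 * signal + rng.normal(0.0, 0.05, n)
    return X, y, informative


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
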