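import numpy as np
import pytest

from bindscape import (
    EnergyMatrix,
    MarkovBackground,
    random_energy_matrix,
    yeast_like_background,
)
from bindscape.background import neutral_energy_spectrum


@pytest.fixture(scope="session")
def uniform_bg():
    return MarkovBackground.uniform()


@pytest.fixture(scope="session")
def yeast_bg():
    return yeast_like_background()


@pytest.fixture(scope="session")
def small_matrix(yeast_bg):
    """Unit-SD random matrix, L=4 (enumerable in tests)."""
    return random_energy_matrix(4, seed=11, background=yeast_bg.mono)


@pytest.fixture(scope="session")
def medium_matrix(yeast_bg):
    """Unit-SD random matrix, L=8 (exact steady-state sampling)."""
    return random_energy_matrix(8, seed=5, background=yeast_bg.mono)


@pytest.fixture(scope="session")
def small_spectrum(yeast_bg, small_matrix):
    return neutral_energy_spectrum(yeast_bg, small_matrix, bin_width=0.02)


@pytest.fixture(scope="session")
def medium_spectrum(yeast_bg, medium_matrix):
    return neutral_energy_spectrum(yeast_bg, medium_matrix, bin_width=0.02)
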