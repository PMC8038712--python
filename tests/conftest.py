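import numpy as np
import pytest

from ftirfp import Spectrum, SpectraSet


@pytest.fixture
def uniform_grid():
    """600..4000 cm^-1 at 1 cm^-1 spacing."""
    return np.arange(600.0, 4001.0)


def gaussian(grid, center, sigma, amplitude=1.0):
    return amplitude * np.exp(-((grid - center) ** 2) / (2.0 * sigma**2))


@pytest.fixture
def gaussian_spectrum(uniform_grid):
    """Factory: spectrum made of Gaussian bands on the 1 cm^-1 grid."""
    def make(bands, sample_id="synthetic"):
        y = np.zeros_like(uniform_grid)
        for center, sigma, amplitude in bands:
            y += gaussian(uniform_grid, center, sigma, amplitude)
        return Spectrum(uniform_grid, y, sample_id=sample_id)
    return make


@pytest.fixture
def small_set():
    """Tiny 4-row SpectraSet on a short grid for I/O and PCA plumbing."""
    rng = np.random.default_rng(42)
    grid = np.arange(1000.0, 1100.0, 2.0)
    mat = rng.normal(size=(4, grid.size))
    return SpectraSet(
        grid=grid, matrix=mat,
        sample_ids=[f"s{i}" for i in range(4)],
        labels=["a", "a", "b", "b"], replicates=[1, 2, 1, 2],
    )
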