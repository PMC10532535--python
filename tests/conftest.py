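import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phycoftir import SampleMeta, Spectrum, canonical_grid

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def gaussian(x: np.ndarray, center: float, height: float, fwhm: float) -> np.ndarray:
    return height * np.exp(-4.0 * np.log(2.0) * ((x - center) / fwhm) ** 2)


@pytest.fixture
def carr_grid() -> np.ndarray:
    """Canonical 0.482 cm^-1 grid over the carrageenan analysis window."""
    return canonical_grid(800.0, 1240.0)


@pytest.fixture
def make_gaussian_spectrum():
    def _make(bands, grid=None, sample_id="synthetic"):
        g = canonical_grid(800.0, 1240.0) if grid is None else np.asarray(grid, float)
        y = np.zeros_like(g)
        for center, height, fwhm in bands:
            y += gaussian(g, center, height, fwhm)
        return Spectrum(g, y, SampleMeta(sample_id=sample_id))
    return _make
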