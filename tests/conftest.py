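import numpy as np
import pytest

from oxspectra import (
    SpectraCollection,
    Spectrum,
    SyntheticConfig,
    generate_cell_spectrum,
)


@pytest.fixture(scope="session")
def grid() -> np.ndarray:
    """Default 800-4000 cm^-1 acquisition grid at 2 cm^-1 step."""
    return np.arange(800.0, 4000.0 + 1.0, 2.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def noiseless_config() -> SyntheticConfig:
    return SyntheticConfig(noise_sd=0.0, cd_noise_sd=0.0, tbars_noise_sd=0.0,
                           cells_millions_jitter=0.0)


@pytest.fixture()
def small_collection(grid) -> SpectraCollection:
    """Three noiseless synthetic spectra in two treatment groups."""
    cfg = SyntheticConfig(noise_sd=0.0)
    return SpectraCollection(
        [
            generate_cell_spectrum(cfg, 0.0, seed=0, sample_id="c1",
                                   treatment="control"),
            generate_cell_spectrum(cfg, 0.0, seed=1, sample_id="c2",
                                   treatment="control"),
            generate_cell_spectrum(cfg, 1.0, seed=2, sample_id="s1",
                                   treatment="H2O2"),
        ]
    )


def gaussian_spectrum(grid, center, amplitude=1.0, sigma=8.0, **kw) -> Spectrum:
    y = amplitude * np.exp(-((grid - center) ** 2) / (2.0 * sigma**2))
    return Spectrum(grid, y, **kw)
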