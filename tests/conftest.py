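import numpy as np
import pytest

from localpls import SpectralDataset, SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_dataset(rng):
    """5 samples x 8 wavelengths with 2-analyte concentrations."""
    wl = 400.0 + 2.0 * np.arange(8)
    A = rng.uniform(0.0, 1.5, size=(5, 8))
    C = rng.uniform(0.0, 200.0, size=(5, 2))
    return SpectralDataset(
        wavelengths=wl,
        absorbance=A,
        concentrations=C,
        sample_ids=[f"mix{i}" for i in range(5)],
        analyte_names=["red", "blue"],
    )


@pytest.fixture
def linear_config():
    """Noiseless Beer-Lambert conditions on a coarse grid (fast tests)."""
    return SyntheticConfig(
        wavelength_step=3.0, noise_sd=0.0, baseline_sd=0.0, drift_sd=0.0, wavelength_jitter_sd=0.0, seed=11
    )
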