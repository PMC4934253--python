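"""Synthetic UV-VIS mixture spectra with overlapping Gaussian bands.

The generator emulates visible-range absorbance measurements of aqueous dye
mixtures: four components with strongly overlapping bands on a 407-605 nm
grid, concentrations spanning 0-200 ug/mL, a design mixing one-, two- and
four-component samples, additive Gaussian noise, a per-sample baseline
offset and smooth background tilt (the "background variations" wavelength
selection is meant to reject), and an optional saturation nonlinearity

    A_obs = A_max * (1 - exp(-A / A_max))

that mimics detector/stray-light compression of strong bands.  In the linear
regime the data obey the Beer-Lambert mixing law A = C . S exactly, so a
non-negative least-squares fit against the true pure spectra is the
noise-floor oracle for any calibration method run on the same data.

Band positions and widths are package constants chosen so that two components
overlap strongly and one broad component overlaps everything; they are
synthetic shapes, not digitized from any instrument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .dataio import SpectralDataset


@dataclass(frozen=True)
class ComponentBand:
    """One Gaussian absorption band: center (nm), sigma (nm), peak height
    in absorbance per (ug/mL)."""

    center_nm: float
    width_nm: float
    peak_molar_absorbance: float

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("width must be positive")
        if self.peak_molar_absorbance <= 0:
            raise ValueError("peak height must be positive")


#: default four-component band set: components 0 and 1 overlap strongly
#: (red dyes), component 2 sits in the blue, component 3 is broad and
#: overlaps all others (synthetic shapes).
DEFAULT_COMPONENTS: tuple[tuple[ComponentBand, ...], ...] = (
    (ComponentBand(521.0, 18.0, 0.0060),),
    (ComponentBand(536.0, 24.0, 0.0055),),
    (ComponentBand(427.0, 16.0, 0.0060),),
    (ComponentBand(482.0, 30.0, 0.0048), ComponentBand(430.0, 14.0, 0.0012)),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study design for one simulated dataset.

    Defaults mirror the measurement conditions the package is built around:
    407-605 nm at 1-nm steps, 4 analytes, 0-200 ug/mL, 97 samples split
    70 calibration / 27 prediction, 10-scan-averaged instrument noise.
    """

    wavelength_start: float = 407.0
    wavelength_stop: float = 605.0
    wavelength_step: float = 1.0
    components: tuple[tuple[ComponentBand, ...], ...] = DEFAULT_COMPONENTS
    conc_max: float = 200.0
    conc_active_min: float = 20.0
    n_samples: int = 97
    n_prediction: int = 27
    noise_sd: float = 0.0016  # 10-scan average of ~0.005 A single-scan noise
    baseline_sd: float = 0.001
    drift_sd: float = 0.0015
    wavelength_jitter_sd: float = 0.05  # scan-to-scan registration error, nm
    full_mix_min: float = 30.0
    full_mix_max: float = 110.0
    saturation_a_max: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wavelength_step <= 0 or self.wavelength_stop <= self.wavelength_start:
            raise ValueError("invalid wavelength grid")
        if self.conc_max <= 0 or not 0 <= self.conc_active_min < self.conc_max:
            raise ValueError("invalid concentration range")
        if min(self.noise_sd, self.baseline_sd, self.drift_sd, self.wavelength_jitter_sd) < 0:
            raise ValueError("noise scales must be non-negative")
        if self.saturation_a_max is not None and self.saturation_a_max <= 0:
            raise ValueError("saturation bound must be positive")
        if self.n_prediction >= self.n_samples:
            raise ValueError("prediction set must be smaller than total")
        grid = self.grid()
        for bands in self.components:
            for b in bands:
                if not grid[0] <= b.center_nm <= grid[-1]:
                    raise ValueError(f"band center {b.center_nm} nm off grid")

    def grid(self) -> np.ndarray:
        n = int(round((self.wavelength_stop - self.wavelength_start) / self.wavelength_step)) + 1
        return self.wavelength_start + self.wavelength_step * np.arange(n)

    @property
    def n_components(self) -> int:
        return len(self.components)


def pure_spectra(config: SyntheticConfig, grid: np.ndarray | None = None) -> np.ndarray:
    """Pure-component absorptivity spectra, shape (q, n), per ug/mL."""
    if grid is None:
        grid = config.grid()
    S = np.zeros((config.n_components, grid.size))
    for ci, bands in enumerate(config.components):
        for b in bands:
            S[ci] += b.peak_molar_absorbance * np.exp(
                -0.5 * ((grid - b.center_nm) / b.width_nm) ** 2
            )
    return S


def _design_concentrations(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Grouped mixture design on a coarse concentration grid.

    Working solutions fall into composition groups the way dilution series
    are prepared in practice: single-component samples, two-component
    mixtures restricted to fixed analyte pairs (the strongly overlapping
    pair and the remaining pair), and full mixtures of all components.
    Active concentrations sit on a 10-ug/mL grid between ``conc_active_min``
    and ``conc_max``; full mixtures use the moderate ``full_mix_min`` to
    ``full_mix_max`` band per analyte (diluting every stock into one volume
    caps how concentrated each can be), so they form a compact cluster.
    Inactive analytes are exactly 0.  The first 2q rows are single-component
    samples at the range top and at a mid concentration, so each analyte
    attains both range endpoints within the calibration set.
    """
    q = config.n_components
    m = config.n_samples
    if m < 2 * q + 1:
        raise ValueError("design needs at least 2q + 1 samples")
    C = np.zeros((m, q))
    for i in range(q):
        C[2 * i, i] = config.conc_max
        C[2 * i + 1, i] = 0.3 * config.conc_max
    pairs = [(i, i + 1) for i in range(0, q - 1, 2)] or [(0, 0)]
    step = 10.0
    lo = max(step, step * round(config.conc_active_min / step))
    levels = np.arange(lo, config.conc_max + 0.5 * step, step)
    full_levels = np.arange(
        max(lo, config.full_mix_min), min(config.conc_max, config.full_mix_max) + 0.5 * step, step
    )
    for r in range(2 * q, m):
        kind = rng.choice(3, p=[0.3, 0.4, 0.3])
        if kind == 0 or q == 1:
            active = [int(rng.integers(q))]
            C[r, active] = rng.choice(levels, size=1)
        elif kind == 1 and q >= 2:
            active = list(pairs[int(rng.integers(len(pairs)))])
            C[r, active] = rng.choice(levels, size=len(active))
        else:
            C[r, :] = rng.choice(full_levels, size=q)
    return C


def _saturate(A: np.ndarray, a_max: float | None) -> np.ndarray:
    if a_max is None:
        return A
    return a_max * (1.0 - np.exp(-A / a_max))


def generate_dataset(config: SyntheticConfig) -> SpectralDataset:
    """Simulate the full working-solution set (calibration + prediction rows).

    A = saturate(C . S) + baseline + noise; reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid()
    C = _design_concentrations(config, rng)
    if config.wavelength_jitter_sd > 0:
        # scan-to-scan wavelength registration error: each sample's spectrum
        # is evaluated on a slightly shifted grid
        shifts = rng.normal(0.0, config.wavelength_jitter_sd, size=C.shape[0])
        A = np.empty((C.shape[0], grid.size))
        for i in range(C.shape[0]):
            A[i] = C[i] @ pure_spectra(config, grid - shifts[i])
    else:
        A = C @ pure_spectra(config)
    A = _saturate(A, config.saturation_a_max)
    if config.baseline_sd > 0:
        A = A + rng.normal(0.0, config.baseline_sd, size=(C.shape[0], 1))
    if config.drift_sd > 0:
        # smooth per-scan background tilt across the wavelength range
        tilt = (grid - grid.mean()) / (grid[-1] - grid[0])
        A = A + rng.normal(0.0, config.drift_sd, size=(C.shape[0], 1)) * tilt[None, :]
    if config.noise_sd > 0:
        A = A + rng.normal(0.0, config.noise_sd, size=A.shape)
    return SpectralDataset(
        wavelengths=config.grid(),
        absorbance=A,
        concentrations=C,
        sample_ids=[f"s{i}" for i in range(C.shape[0])],
        analyte_names=[f"analyte{i}" for i in range(config.n_components)],
    )


def generate_split(config: SyntheticConfig) -> tuple[SpectralDataset, SpectralDataset]:
    """Simulate and randomly split into (calibration, prediction) sets.

    The coverage block stays in calibration so the calibration set spans the
    full concentration range of every analyte.
    """
    from .dataio import split_dataset

    ds = generate_dataset(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 977]))
    q = config.n_components
    eligible = np.arange(2 * q, config.n_samples)
    pred_idx = np.sort(rng.choice(eligible, size=config.n_prediction, replace=False))
    return split_dataset(ds, pred_idx)


def oracle_predict(dataset: SpectralDataset, config: SyntheticConfig) -> np.ndarray:
    """Noise-floor reference: non-negative least squares against the true
    pure spectra (valid in the linear regime; biased under saturation)."""
    S = pure_spectra(config)
    if dataset.n_wavelengths != S.shape[1] or not np.allclose(
        dataset.wavelengths, config.grid()
    ):
        raise ValueError("dataset grid does not match the generator config")
    C = np.zeros((dataset.n_samples, S.shape[0]))
    for i in range(dataset.n_samples):
        C[i], _ = nnls(S.T, dataset.absorbance[i])
    return C
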