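"""Spectral dataset container, CSV I/O, Savitzky-Golay smoothing and set splitting.

The in-memory currency of the package is :class:`SpectralDataset`: a wavelength
axis in nm, an absorbance matrix (samples x wavelengths) and, for calibration
data, a concentration matrix (samples x analytes, ug/mL).

File format is plain CSV.  The header row lists an ``id`` column, the
wavelengths in nm, and optionally trailing analyte columns whose headers carry
a ``conc:`` prefix (e.g. ``conc:amaranth``).  All writers emit the same
dialect, so write -> read is the identity on valid datasets.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import savgol_filter


class SpectralIOError(ValueError):
    """Base class for spectral file-format errors."""


class NonNumericCellError(SpectralIOError):
    """A cell that should be numeric could not be parsed."""


class NonIncreasingWavelengthsError(SpectralIOError):
    """The wavelength header is not strictly increasing."""


class RowLengthMismatchError(SpectralIOError):
    """A data row has a different number of fields than the header."""


class InvalidDatasetError(ValueError):
    """A SpectralDataset invariant is violated."""


@dataclass
class SpectralDataset:
    """Spectra on a common wavelength grid, with optional concentrations.

    Parameters
    ----------
    wavelengths : ndarray, shape (n,)
        Strictly increasing wavelength axis in nm.
    absorbance : ndarray, shape (m, n)
        One spectrum per row, absorbance units.
    concentrations : ndarray, shape (m, q), optional
        Analyte concentrations in ug/mL; non-negative.
    sample_ids : list of str, optional
        Defaults to ``s0 .. s{m-1}``.
    analyte_names : list of str, optional
        Defaults to ``analyte0 .. analyte{q-1}`` when concentrations exist.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    concentrations: np.ndarray | None = None
    sample_ids: list[str] = field(default_factory=list)
    analyte_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.wavelengths.ndim != 1:
            raise InvalidDatasetError("wavelengths must be one-dimensional")
        if self.absorbance.shape[1] != self.wavelengths.size:
            raise InvalidDatasetError(
                f"absorbance has {self.absorbance.shape[1]} columns but "
                f"{self.wavelengths.size} wavelengths were given"
            )
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise NonIncreasingWavelengthsError(
                "wavelength axis must be strictly increasing"
            )
        if not np.all(np.isfinite(self.wavelengths)) or not np.all(
            np.isfinite(self.absorbance)
        ):
            raise InvalidDatasetError("non-finite entries in spectral data")
        m = self.absorbance.shape[0]
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(m)]
        if len(self.sample_ids) != m:
            raise InvalidDatasetError(
                f"{len(self.sample_ids)} sample ids for {m} spectra"
            )
        if self.concentrations is not None:
            self.concentrations = np.atleast_2d(
                np.asarray(self.concentrations, dtype=float)
            )
            if self.concentrations.shape[0] != m:
                raise InvalidDatasetError("concentration rows != spectra rows")
            if not np.all(np.isfinite(self.concentrations)):
                raise InvalidDatasetError("non-finite concentrations")
            if np.any(self.concentrations < 0):
                raise InvalidDatasetError("concentrations must be non-negative")
            q = self.concentrations.shape[1]
            if self.analyte_names is None:
                self.analyte_names = [f"analyte{i}" for i in range(q)]
            if len(self.analyte_names) != q:
                raise InvalidDatasetError("analyte_names length != analyte count")

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    @property
    def n_analytes(self) -> int:
        return 0 if self.concentrations is None else self.concentrations.shape[1]

    def equals(self, other: "SpectralDataset") -> bool:
        """Field-by-field equality (exact array comparison)."""
        if not isinstance(other, SpectralDataset):
            return False
        if self.sample_ids != other.sample_ids:
            return False
        if (self.analyte_names or None) != (other.analyte_names or None):
            return False
        if not np.array_equal(self.wavelengths, other.wavelengths):
            return False
        if not np.array_equal(self.absorbance, other.absorbance):
            return False
        if (self.concentrations is None) != (other.concentrations is None):
            return False
        if self.concentrations is not None and not np.array_equal(
            self.concentrations, other.concentrations
        ):
            return False
        return True

    def take(self, indices) -> "SpectralDataset":
        """Row subset in the given order."""
        indices = np.asarray(indices, dtype=int)
        conc = None if self.concentrations is None else self.concentrations[indices]
        return SpectralDataset(
            wavelengths=self.wavelengths.copy(),
            absorbance=self.absorbance[indices].copy(),
            concentrations=conc,
            sample_ids=[self.sample_ids[i] for i in indices],
            analyte_names=None if self.analyte_names is None else list(self.analyte_names),
        )


@dataclass(frozen=True)
class SmoothingParams:
    """Savitzky-Golay smoothing parameters: polynomial degree and odd window."""

    poly_degree: int = 2
    window: int = 21

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise ValueError("window must be odd")
        if self.window <= self.poly_degree:
            raise ValueError("window must exceed polynomial degree")
        if self.poly_degree < 0:
            raise ValueError("polynomial degree must be >= 0")


def read_spectra(path, has_concentrations: bool = False) -> SpectralDataset:
    """Read a CSV spectral file.

    The header must contain an ``id`` column first (optional), then the
    wavelengths in nm, then any number of trailing ``conc:<analyte>`` columns.

    Parameters
    ----------
    path : path-like
    has_concentrations : bool
        When True, the file is required to carry ``conc:`` columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    rows = [r for r in rows if r and any(c.strip() for c in r)]
    if not rows:
        raise SpectralIOError(f"{path}: empty file")
    header = [c.strip() for c in rows[0]]
    start = 0
    has_ids = header and header[0].lower() == "id"
    if has_ids:
        start = 1
    conc_cols = [i for i, h in enumerate(header) if h.startswith("conc:")]
    if conc_cols and conc_cols != list(range(conc_cols[0], len(header))):
        raise SpectralIOError(f"{path}: conc: columns must be trailing")
    n_conc = len(conc_cols)
    if has_concentrations and n_conc == 0:
        raise SpectralIOError(f"{path}: no conc: columns found")
    wl_cells = header[start : len(header) - n_conc]
    if not wl_cells:
        raise SpectralIOError(f"{path}: no wavelength columns")
    try:
        wavelengths = np.array([float(c) for c in wl_cells])
    except ValueError as exc:
        raise NonNumericCellError(f"{path}: bad wavelength header: {exc}") from None
    if wavelengths.size >= 2 and not np.all(np.diff(wavelengths) > 0):
        raise NonIncreasingWavelengthsError(
            f"{path}: wavelength header not strictly increasing"
        )
    analyte_names = [header[i][len("conc:") :] for i in conc_cols] or None

    ids: list[str] = []
    spectra: list[list[float]] = []
    concs: list[list[float]] = []
    width = len(header)
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise RowLengthMismatchError(
                f"{path}:{lineno}: {len(row)} fields, expected {width}"
            )
        cells = [c.strip() for c in row]
        if has_ids:
            ids.append(cells[0])
        try:
            values = [float(c) for c in cells[start:]]
        except ValueError as exc:
            raise NonNumericCellError(f"{path}:{lineno}: {exc}") from None
        if n_conc:
            spectra.append(values[:-n_conc])
            concs.append(values[-n_conc:])
        else:
            spectra.append(values)
    return SpectralDataset(
        wavelengths=wavelengths,
        absorbance=np.array(spectra, dtype=float),
        concentrations=np.array(concs, dtype=float) if n_conc else None,
        sample_ids=ids if has_ids else [],
        analyte_names=analyte_names,
    )


def write_spectra(ds: SpectralDataset, path) -> None:
    """Write a dataset in the package CSV dialect (exact float round-trip)."""
    path = Path(path)
    header = ["id"] + [repr(float(w)) for w in ds.wavelengths]
    if ds.concentrations is not None:
        header += [f"conc:{name}" for name in ds.analyte_names]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for i in range(ds.n_samples):
            row = [ds.sample_ids[i]] + [repr(float(v)) for v in ds.absorbance[i]]
            if ds.concentrations is not None:
                row += [repr(float(v)) for v in ds.concentrations[i]]
            writer.writerow(row)


def _edge_fit_weights(length: int, target: int, degree: int) -> np.ndarray:
    """Weights of the least-squares polynomial fit over positions 0..length-1
    evaluated at ``target``."""
    pos = np.arange(length, dtype=float) - target
    V = np.vander(pos, degree + 1, increasing=True)
    # fitted value at target = e0 . pinv(V) y
    return np.linalg.pinv(V)[0]


def sg_smooth(ds: SpectralDataset, params: SmoothingParams | None = None) -> SpectralDataset:
    """Savitzky-Golay smoothing of every spectrum.

    Interior points use the standard central-window convolution; the first and
    last ``l`` points (l = half window) are fitted on the truncated one-sided
    window so the output keeps the input length without reflection padding.
    Wavelengths and concentrations are unchanged.
    """
    if params is None:
        params = SmoothingParams()
    n = ds.n_wavelengths
    if params.window > n:
        raise ValueError(f"window {params.window} exceeds {n} wavelengths")
    A = ds.absorbance
    smoothed = savgol_filter(A, params.window, params.poly_degree, axis=1, mode="interp")
    half = params.window // 2
    for i in range(half):
        # left edge: window [0, i + half]
        L = i + half + 1
        w = _edge_fit_weights(L, i, params.poly_degree)
        smoothed[:, i] = A[:, :L] @ w
        # right edge, mirrored
        w = _edge_fit_weights(L, L - 1 - i, params.poly_degree)
        smoothed[:, n - 1 - i] = A[:, n - L :] @ w
    return replace(ds, absorbance=smoothed, wavelengths=ds.wavelengths.copy())


def split_dataset(ds: SpectralDataset, prediction_indices) -> tuple[SpectralDataset, SpectralDataset]:
    """Split into (calibration, prediction) datasets by row indices.

    ``prediction_indices`` select the prediction rows (0-based); the remaining
    rows, in original order, form the calibration set.
    """
    idx = np.asarray(list(prediction_indices), dtype=int)
    m = ds.n_samples
    if idx.size != np.unique(idx).size:
        raise IndexError("duplicate prediction indices")
    if idx.size and (idx.min() < 0 or idx.max() >= m):
        raise IndexError(f"prediction index out of range for {m} samples")
    mask = np.ones(m, dtype=bool)
    mask[idx] = False
    cal = ds.take(np.nonzero(mask)[0])
    pred = ds.take(idx)
    return cal, pred
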