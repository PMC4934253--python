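"""Pure-variable (wavelength) selection by SIMPLISMA.

SIMPLISMA scores each wavelength by a purity ratio sigma/(mu + alpha) — large
where a single mixture component dominates, small where several components or
only baseline contribute — and iteratively picks the purest wavelength while a
determinant weight built on the correlation-around-the-origin matrix removes
everything correlated with wavelengths already chosen.  The relative total
intensity Rs_j of the successive standard-deviation spectra collapses toward
zero once the selected wavelengths span the mixture, so the ratio
Rs_{j+1}/Rs_j dropping below a threshold stops the search without any
cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class NoInformativeVariableError(ValueError):
    """Every column has zero variance: no pure variable exists."""


@dataclass(frozen=True)
class SimplismaParams:
    """Noise offset and stop rule.

    alpha_percent : noise offset alpha as a fraction of the maximum column
        mean (1% typical; 1-5% sensible).
    rs_threshold : stop threshold tau on the relative total intensity
        Rs_{j+1} of the next standard-deviation spectrum (Rs_1 = 1 by
        definition).  Selection ends at j once Rs_{j+1} < tau, i.e. once the
        next spectrum carries essentially none of the initial intensity and
        the determining coefficient R_j = Rs_j / Rs_{j+1} spikes.
    max_pure_variables : hard cap on the number of selected wavelengths; when
        None it defaults per matrix to min(m - 1, n, 30).
    """

    alpha_percent: float = 0.01
    rs_threshold: float = 2e-5
    max_pure_variables: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_percent <= 0.05:
            raise ValueError("alpha_percent must lie in (0, 0.05]")
        if self.rs_threshold <= 0.0:
            raise ValueError("rs_threshold must be positive")
        if self.max_pure_variables is not None and self.max_pure_variables < 1:
            raise ValueError("max_pure_variables must be >= 1")


@dataclass
class SimplismaResult:
    """Selection trace: indices, purity/sd spectra per step, Rs and R traces."""

    pure_variable_indices: list[int]
    purity_spectra: list[np.ndarray]
    sd_spectra: list[np.ndarray]
    rs_trace: np.ndarray  # Rs_1 .. Rs_{J+1} (last value if computed)
    determining_trace: np.ndarray  # R_1 .. R_J  (R_j = Rs_j / Rs_{j+1})
    stop_j: int

    def to_frame(self, wavelengths=None):
        """Per-step table (step, wavelength, purity, sd intensity, Rs, R)."""
        import pandas as pd

        rows = []
        for step, idx in enumerate(self.pure_variable_indices, start=1):
            rows.append(
                {
                    "step": step,
                    "wavelength_index": idx,
                    "wavelength_nm": float(wavelengths[idx]) if wavelengths is not None else np.nan,
                    "purity": float(self.purity_spectra[step - 1][idx]),
                    "sd_intensity": float(self.sd_spectra[step - 1][idx]),
                    "Rs": float(self.rs_trace[step - 1]),
                    "R": float(self.determining_trace[step - 1])
                    if step - 1 < len(self.determining_trace)
                    else np.nan,
                }
            )
        return pd.DataFrame(rows)


def column_stats(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column means and population (1/m) standard deviations."""
    D = np.atleast_2d(np.asarray(D, dtype=float))
    if D.size == 0:
        raise ValueError("empty data matrix")
    return D.mean(axis=0), D.std(axis=0)  # ddof=0: population normalisation


def _alpha_value(means: np.ndarray, params: SimplismaParams) -> float:
    return params.alpha_percent * float(means.max())


def correlation_around_origin(D: np.ndarray, alpha: float) -> np.ndarray:
    """Correlation-around-the-origin matrix C (n x n).

    Each column i is scaled by its length lambda_i = sqrt(mu_i^2 +
    (sigma_i + alpha)^2); C = (1/m) * D_scaled^T D_scaled is symmetric PSD
    with entries bounded by 1 in magnitude.
    """
    D = np.atleast_2d(np.asarray(D, dtype=float))
    mu, sigma = column_stats(D)
    lam = np.sqrt(mu**2 + (sigma + alpha) ** 2)
    Ds = D / lam[None, :]
    return (Ds.T @ Ds) / D.shape[0]


def _determinant_weights(C: np.ndarray, selected: list[int]) -> np.ndarray:
    """w_i = det of the bordered submatrix of C on indices (i, p_1..p_{j-1}).

    With no prior selection the weight is 1 everywhere.  Vectorised as a
    batched determinant over all candidate wavelengths i.
    """
    n = C.shape[0]
    j = len(selected) + 1
    if j == 1:
        return np.ones(n)
    P = np.asarray(selected, dtype=int)
    M = np.empty((n, j, j))
    M[:, 0, 0] = np.diag(C)
    M[:, 0, 1:] = C[:, P]
    M[:, 1:, 0] = C[:, P]
    M[:, 1:, 1:] = C[np.ix_(P, P)][None, :, :]
    return np.linalg.det(M)


def purity_step(
    D: np.ndarray, already_selected: list[int], params: SimplismaParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Purity and standard-deviation spectra for the next selection step.

    purity_i = w_i * sigma_i / (mu_i + alpha);  sd_i = sigma_i * w_i, where
    w_i is the determinant weight that vanishes at (and decorrelates from)
    already-selected wavelengths.
    """
    if params is None:
        params = SimplismaParams()
    if len(set(already_selected)) != len(already_selected):
        raise ValueError("repeated index in already_selected")
    D = np.atleast_2d(np.asarray(D, dtype=float))
    mu, sigma = column_stats(D)
    alpha = _alpha_value(mu, params)
    C = correlation_around_origin(D, alpha)
    w = _determinant_weights(C, list(already_selected))
    purity = w * sigma / (mu + alpha)
    sd = sigma * w
    return purity, sd


def select_pure_variables(D: np.ndarray, params: SimplismaParams | None = None) -> SimplismaResult:
    """Iterative pure-variable selection with the Rs stop rule.

    At each step the wavelength with the highest purity is selected (ties to
    the lowest index).  After step j the next standard-deviation spectrum is
    evaluated: if its relative total intensity Rs_{j+1} has dropped below
    tau (the next spectrum is essentially noise and R_j spikes), selection
    stops with J = j; otherwise it continues up to the cap.
    """
    if params is None:
        params = SimplismaParams()
    D = np.atleast_2d(np.asarray(D, dtype=float))
    m, n = D.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 samples and 2 wavelengths")
    mu, sigma = column_stats(D)
    if not np.any(sigma > 0.0):
        raise NoInformativeVariableError("all columns constant")
    alpha = _alpha_value(mu, params)
    C = correlation_around_origin(D, alpha)
    base_purity = sigma / (mu + alpha)
    cap = params.max_pure_variables
    if cap is None:
        cap = min(m - 1, n, 30)
    cap = max(1, min(cap, n))

    selected: list[int] = []
    purity_spectra: list[np.ndarray] = []
    sd_spectra: list[np.ndarray] = []
    rs_vals: list[float] = []
    r_vals: list[float] = []
    tau = params.rs_threshold

    sd_total_1: float | None = None
    while True:
        w = _determinant_weights(C, selected)
        purity = w * base_purity
        sd = sigma * w
        purity_spectra.append(purity)
        sd_spectra.append(sd)
        total = float(sd.sum())
        if sd_total_1 is None:
            sd_total_1 = total
            if total <= 0.0:
                raise NoInformativeVariableError("zero total standard deviation")
        rs = total / sd_total_1
        rs_vals.append(rs)
        j = len(selected) + 1
        if j > cap:
            # this step's spectrum was only computed to close the Rs trace
            purity_spectra.pop()
            sd_spectra.pop()
            rs_here = rs_vals[-2]
            r_vals.append(np.inf if rs == 0.0 else rs_here / rs)
            break
        if j > 1:
            prev = rs_vals[-2]
            r_vals.append(np.inf if rs == 0.0 else prev / rs)
            if rs < tau:
                # step j's spectrum is noise: keep J = j - 1 selections
                purity_spectra.pop()
                sd_spectra.pop()
                break
        selected.append(int(np.argmax(purity)))

    return SimplismaResult(
        pure_variable_indices=selected,
        purity_spectra=purity_spectra,
        sd_spectra=sd_spectra,
        rs_trace=np.asarray(rs_vals),
        determining_trace=np.asarray(r_vals),
        stop_j=len(selected),
    )
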