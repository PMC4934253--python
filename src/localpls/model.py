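"""Model/Results surface over the local-calibration pipeline.

``LocalCalibrationModel`` is built from a calibration :class:`SpectralDataset`
(optionally via :meth:`from_csv`); its :meth:`fit` runs the per-query local
procedure on a prediction dataset and returns a
:class:`LocalCalibrationResults` carrying the predicted concentrations,
per-query provenance (subset size, selected wavelengths, factor count),
per-analyte RMSEP when reference concentrations are available, and a
``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataio import SpectralDataset, read_spectra, sg_smooth
from .pipeline import LocalPrediction, PipelineConfig, global_predict, predict_local
from .plsr import rmsep


class LocalCalibrationModel:
    """Local PLS calibration bound to one calibration dataset.

    Parameters
    ----------
    calibration : SpectralDataset
        Must carry concentrations.
    config : PipelineConfig, optional
        Similarity criterion, sweep bounds, SIMPLISMA and PLS settings.
    smooth : bool
        Apply the configured Savitzky-Golay smoothing to the calibration
        spectra on construction (queries passed to ``fit`` are smoothed with
        the same parameters).
    """

    def __init__(
        self,
        calibration: SpectralDataset,
        config: PipelineConfig | None = None,
        smooth: bool = False,
    ):
        if calibration.concentrations is None:
            raise ValueError("calibration dataset lacks concentrations")
        self.config = config or PipelineConfig()
        self._smooth = smooth and self.config.smoothing is not None
        self.calibration = (
            sg_smooth(calibration, self.config.smoothing) if self._smooth else calibration
        )

    @classmethod
    def from_csv(cls, path, config: PipelineConfig | None = None, smooth: bool = False):
        return cls(read_spectra(path, has_concentrations=True), config=config, smooth=smooth)

    def fit(self, queries: SpectralDataset) -> "LocalCalibrationResults":
        """Predict every query spectrum with its own local model."""
        if not np.array_equal(queries.wavelengths, self.calibration.wavelengths):
            raise ValueError("query wavelength grid differs from calibration grid")
        qds = sg_smooth(queries, self.config.smoothing) if self._smooth else queries
        if self.config.method == "global":
            yhat, k = global_predict(qds.absorbance, self.calibration, self.config)
            provenance: list[LocalPrediction | None] = [None] * qds.n_samples
        else:
            provenance = []
            yhat = np.zeros((qds.n_samples, self.calibration.n_analytes))
            for i in range(qds.n_samples):
                lp = predict_local(
                    qds.absorbance[i],
                    self.calibration,
                    self.config,
                    query_id=qds.sample_ids[i],
                )
                provenance.append(lp)
                yhat[i] = lp.predicted_concentrations
        return LocalCalibrationResults(self, qds, yhat, provenance)


class LocalCalibrationResults:
    """Predictions, provenance and error metrics for one fitted query set."""

    def __init__(self, model, queries, predicted, provenance):
        self.model = model
        self.queries = queries
        self.predicted = predicted
        self.provenance = provenance
        names = model.calibration.analyte_names
        self.predictions = pd.DataFrame(
            predicted, index=queries.sample_ids, columns=names
        )
        self.rmsep_ = (
            None
            if queries.concentrations is None
            else pd.Series(rmsep(queries.concentrations, predicted), index=names)
        )

    @property
    def provenance_table(self) -> pd.DataFrame:
        rows = []
        for i, sid in enumerate(self.queries.sample_ids):
            lp = self.provenance[i]
            if lp is None:
                rows.append(
                    {
                        "sample": sid,
                        "subset_size": self.model.calibration.n_samples,
                        "n_wavelengths": self.model.calibration.n_wavelengths,
                        "n_factors": np.nan,
                    }
                )
            else:
                rows.append(
                    {
                        "sample": sid,
                        "subset_size": lp.subset_size,
                        "n_wavelengths": lp.n_wavelengths,
                        "n_factors": lp.n_factors,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Local PLS calibration results",
            "=" * 60,
            f"similarity criterion : {cfg.method}",
            f"wavelength selection : {'SIMPLISMA' if cfg.wavelength_selection else 'off'}",
            f"calibration samples  : {self.model.calibration.n_samples}",
            f"prediction samples   : {self.queries.n_samples}",
            "",
            "Per-sample provenance",
            "-" * 60,
            self.provenance_table.to_string(index=False),
        ]
        if self.rmsep_ is not None:
            lines += [
                "",
                "Per-analyte RMSEP (ug/mL)",
                "-" * 60,
                self.rmsep_.round(4).to_string(),
            ]
        return "\n".join(lines) + "\n"

    def plot_predictions(self, ax=None):
        """Predicted vs reference concentrations (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if self.queries.concentrations is None:
            raise ValueError("no reference concentrations to plot against")
        if ax is None:
            _, ax = plt.subplots()
        for j, name in enumerate(self.predictions.columns):
            ax.scatter(
                self.queries.concentrations[:, j], self.predicted[:, j], s=12, label=name
            )
        lim = [0, max(float(self.queries.concentrations.max()), 1.0)]
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel("reference (ug/mL)")
        ax.set_ylabel("predicted (ug/mL)")
        ax.legend()
        return ax
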