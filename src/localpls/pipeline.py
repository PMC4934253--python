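"""Per-query local calibration: rank -> size sweep -> wavelength selection ->
PLS -> predict, plus batch evaluation against comparator criteria.

For each prediction spectrum the calibration set is sorted by similarity, the
subset size is swept from a small start up to the full set with the
leave-one-out RMSECV of a PLS model on each prefix (full spectra), and the
size minimising RMSECV wins.  SIMPLISMA then picks the informative
wavelengths of the chosen subset, and a PLS model with the PRESS-rule factor
count predicts the query.  ``evaluate`` runs this per-query procedure for a
list of similarity criteria next to a global full-spectrum PLS baseline and
reports per-analyte RMSEP plus a per-sample provenance table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataio import SpectralDataset, SmoothingParams
from .plsr import fit_pls, press_trace, rmsecv_loo, rmsep, select_factors
from .similarity import (
    GRCParams,
    MahalanobisParams,
    SimilarityRanking,
    rank_calibration,
    score_query,
)
from .simplisma import SimplismaParams, select_pure_variables

logger = logging.getLogger(__name__)

METHODS = ("sgrc", "euclidean", "mahalanobis", "angle", "global")


class PipelineStageError(RuntimeError):
    """Failure inside one named stage of the local pipeline."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the local pipeline needs besides the data."""

    method: str = "sgrc"
    grc: GRCParams = field(default_factory=GRCParams)
    mahalanobis: MahalanobisParams = field(default_factory=MahalanobisParams)
    simplisma: SimplismaParams = field(default_factory=SimplismaParams)
    smoothing: SmoothingParams | None = None
    wavelength_selection: bool = True
    sweep_start: int = 3
    sweep_stop: int | None = None  # None -> calibration size
    sweep_step: int = 1
    kmax: int = 15
    factor_rule: str = "pooled_press"
    press_ratio_threshold: float = 1.0
    select_before_sizing: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.sweep_start < 3:
            raise ValueError("sweep_start must be >= 3")
        if self.sweep_step < 1:
            raise ValueError("sweep_step must be >= 1")
        if self.kmax < 1:
            raise ValueError("kmax must be >= 1")


@dataclass
class SubsetSweepResult:
    """RMSECV curve over candidate subset sizes and the chosen minimum."""

    sizes: np.ndarray
    rmsecv_curve: np.ndarray
    chosen_size: int

    def plot(self, ax=None):
        """RMSECV vs subset size (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.sizes, self.rmsecv_curve, marker="o", ms=3)
        ax.axvline(self.chosen_size, ls="--", color="gray")
        ax.set_xlabel("samples in calibration subset")
        ax.set_ylabel("RMSECV (ug/mL)")
        return ax


@dataclass
class LocalPrediction:
    """Prediction for one query plus full provenance."""

    query_id: str
    subset_indices: np.ndarray
    subset_scores: np.ndarray
    selected_wavelength_indices: np.ndarray
    n_factors: int
    predicted_concentrations: np.ndarray
    sweep: SubsetSweepResult | None = None
    ranking: SimilarityRanking | None = None

    @property
    def subset_size(self) -> int:
        return int(self.subset_indices.size)

    @property
    def n_wavelengths(self) -> int:
        return int(self.selected_wavelength_indices.size)


def _rank_query(query: np.ndarray, cal: np.ndarray, config: PipelineConfig, query_id: str = "") -> SimilarityRanking:
    scores = score_query(
        query, cal, config.method, grc=config.grc, mahalanobis=config.mahalanobis
    )
    return rank_calibration(scores, config.method, query_id=query_id)


def sweep_subset_size(
    ranking: SimilarityRanking,
    Xc: np.ndarray,
    Yc: np.ndarray,
    config: PipelineConfig | None = None,
) -> SubsetSweepResult:
    """Choose the calibration-subset size by the LOO RMSECV minimum.

    Each candidate size N takes the top-N samples of the ranking and scores a
    full-spectrum PLS model by leave-one-out RMSECV; ties resolve toward the
    smaller (more parsimonious) subset.  Degenerate prefixes (constant
    responses) are skipped with a log message.

    With ``config.select_before_sizing`` (and wavelength selection enabled),
    each candidate subset is first reduced to its SIMPLISMA wavelengths and
    the RMSECV scores the reduced model, so the chosen size is consistent
    with the model that will actually predict the query.
    """
    if config is None:
        config = PipelineConfig()
    Xc = np.atleast_2d(np.asarray(Xc, dtype=float))
    Yc = np.atleast_2d(np.asarray(Yc, dtype=float))
    m_c = Xc.shape[0]
    stop = m_c if config.sweep_stop is None else min(config.sweep_stop, m_c)
    if m_c < config.sweep_start:
        raise ValueError("calibration set smaller than sweep start")
    sizes = np.arange(config.sweep_start, stop + 1, config.sweep_step)
    curve = np.full(sizes.size, np.nan)
    for i, N in enumerate(sizes):
        idx = ranking.order[:N]
        Ysub = Yc[idx]
        if np.allclose(Ysub, Ysub[0]):
            logger.info("subset size %d skipped: constant responses", N)
            continue
        Xsub = Xc[idx]
        if config.select_before_sizing and config.wavelength_selection:
            try:
                sel = select_pure_variables(Xsub, config.simplisma)
                Xsub = Xsub[:, np.sort(np.unique(sel.pure_variable_indices))]
            except Exception:  # degenerate subset: score on full spectra
                logger.info("subset size %d: wavelength selection failed", N)
        # cap factors at half the training-fold size so the LOO score of a
        # tiny subset measures generalization, not interpolation
        kmax = max(1, min(config.kmax, (N - 2) // 2, Xsub.shape[1]))
        curve[i] = rmsecv_loo(
            Xsub, Ysub, kmax=kmax, factor_rule=config.factor_rule,
            ratio_threshold=config.press_ratio_threshold,
        )
    if np.all(np.isnan(curve)):
        raise ValueError("every candidate subset was degenerate")
    chosen = int(sizes[np.nanargmin(curve)])
    return SubsetSweepResult(sizes=sizes, rmsecv_curve=curve, chosen_size=chosen)


def predict_local(
    query: np.ndarray,
    calibration: SpectralDataset,
    config: PipelineConfig | None = None,
    query_id: str = "",
) -> LocalPrediction:
    """Full local-calibration prediction of one (already smoothed) query."""
    if config is None:
        config = PipelineConfig()
    if calibration.concentrations is None:
        raise ValueError("calibration dataset lacks concentrations")
    query = np.asarray(query, dtype=float).ravel()
    Xc = calibration.absorbance
    Yc = calibration.concentrations

    try:
        ranking = _rank_query(query, Xc, config, query_id=query_id)
    except Exception as exc:  # noqa: BLE001 - stage naming contract
        raise PipelineStageError("similarity", exc) from exc
    try:
        sweep = sweep_subset_size(ranking, Xc, Yc, config)
    except Exception as exc:
        raise PipelineStageError("subset-sweep", exc) from exc

    subset_idx = ranking.order[: sweep.chosen_size]
    Xsub = Xc[subset_idx]
    Ysub = Yc[subset_idx]

    if config.wavelength_selection:
        try:
            sim = select_pure_variables(Xsub, config.simplisma)
            wl_idx = np.asarray(sim.pure_variable_indices, dtype=int)
        except Exception as exc:
            raise PipelineStageError("wavelength-selection", exc) from exc
    else:
        wl_idx = np.arange(Xc.shape[1])

    cols = np.sort(np.unique(wl_idx))
    try:
        Xw = Xsub[:, cols]
        # same conservative ceiling as the sweep: LOO-PRESS on N samples can
        # support about half as many factors as training-fold samples
        kmax = max(1, min(config.kmax, (Xw.shape[0] - 2) // 2, cols.size))
        press = press_trace(Xw, Ysub, kmax)
        k = select_factors(press, config.press_ratio_threshold)
        model = fit_pls(Xw, Ysub, k)
        model.press_trace = press
        yhat = model.predict(query[cols][None, :])[0]
    except Exception as exc:
        raise PipelineStageError("pls", exc) from exc

    return LocalPrediction(
        query_id=query_id,
        subset_indices=subset_idx,
        subset_scores=ranking.scores[: sweep.chosen_size],
        selected_wavelength_indices=wl_idx,
        n_factors=model.n_factors,
        predicted_concentrations=yhat,
        sweep=sweep,
        ranking=ranking,
    )


def global_predict(
    queries: np.ndarray, calibration: SpectralDataset, config: PipelineConfig | None = None
) -> tuple[np.ndarray, int]:
    """Global full-spectrum PLS baseline: one model for all queries.

    Returns (predictions, n_factors); the factor count follows the same
    PRESS first-upturn rule used inside the local pipeline.
    """
    if config is None:
        config = PipelineConfig()
    if calibration.concentrations is None:
        raise ValueError("calibration dataset lacks concentrations")
    X = calibration.absorbance
    Y = calibration.concentrations
    kmax = max(1, min(config.kmax, X.shape[0] - 2, X.shape[1]))
    press = press_trace(X, Y, kmax)
    k = select_factors(press, config.press_ratio_threshold)
    model = fit_pls(X, Y, k)
    model.press_trace = press
    return model.predict(np.atleast_2d(queries)), model.n_factors


@dataclass
class EvaluationReport:
    """Comparator study output: per-method RMSEP and per-sample provenance."""

    rmsep_table: pd.DataFrame  # index: method, columns: analytes
    per_sample: pd.DataFrame  # method, sample, subset size, wavelengths, factors
    predictions: dict[str, np.ndarray]

    def summary(self) -> str:
        lines = ["Per-analyte RMSEP (ug/mL)", "-" * 60]
        lines.append(self.rmsep_table.round(4).to_string())
        lines.append("")
        lines.append("Per-sample calibration-subset provenance")
        lines.append("-" * 60)
        lines.append(self.per_sample.to_string(index=False))
        return "\n".join(lines) + "\n"


def evaluate(
    prediction_set: SpectralDataset,
    calibration_set: SpectralDataset,
    methods=("sgrc", "global"),
    config: PipelineConfig | None = None,
) -> EvaluationReport:
    """Run the listed criteria on every prediction sample and score RMSEP."""
    if config is None:
        config = PipelineConfig()
    if prediction_set.concentrations is None:
        raise ValueError("prediction set lacks reference concentrations")
    for method in methods:
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}")
    analytes = calibration_set.analyte_names or [
        f"analyte{i}" for i in range(calibration_set.n_analytes)
    ]
    n_full = calibration_set.n_wavelengths
    rows = []
    rmsep_rows = {}
    predictions: dict[str, np.ndarray] = {}
    for method in methods:
        if method == "global":
            yhat, k = global_predict(prediction_set.absorbance, calibration_set, config)
            for i, sid in enumerate(prediction_set.sample_ids):
                rows.append(
                    {
                        "method": method,
                        "sample": sid,
                        "subset_size": calibration_set.n_samples,
                        "n_wavelengths": n_full,
                        "n_factors": k,
                    }
                )
        else:
            local_cfg = replace(config, method=method)
            yhat = np.zeros_like(np.atleast_2d(prediction_set.concentrations), dtype=float)
            for i, sid in enumerate(prediction_set.sample_ids):
                lp = predict_local(
                    prediction_set.absorbance[i], calibration_set, local_cfg, query_id=sid
                )
                yhat[i] = lp.predicted_concentrations
                rows.append(
                    {
                        "method": method,
                        "sample": sid,
                        "subset_size": lp.subset_size,
                        "n_wavelengths": lp.n_wavelengths,
                        "n_factors": lp.n_factors,
                    }
                )
        predictions[method] = yhat
        rmsep_rows[method] = rmsep(prediction_set.concentrations, yhat)
    table = pd.DataFrame.from_dict(rmsep_rows, orient="index", columns=analytes)
    table.index.name = "method"
    return EvaluationReport(
        rmsep_table=table, per_sample=pd.DataFrame(rows), predictions=predictions
    )
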