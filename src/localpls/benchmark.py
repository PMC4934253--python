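"""Desk-scale benchmark definitions shared by the test suite and the
acceptance script.

The benchmark runs the full default study conditions — 70 + 27 samples,
407-605 nm at 1 nm, Savitzky-Golay degree 2 / window 21, SIMPLISMA noise
offset 1% with Rs threshold 2e-5 — with two economies that keep a
multi-seed comparison in minutes on one CPU: the subset-size sweep starts at
5 samples (one of the three canonical start values), advances in steps of 3,
and scores each candidate subset on its SIMPLISMA-selected wavelengths
(selection-aware sizing), so the chosen size matches the model that finally
predicts the query.
"""

from __future__ import annotations

import numpy as np

from .dataio import SmoothingParams, sg_smooth
from .pipeline import PipelineConfig, evaluate
from .plsr import rmsep
from .simplisma import SimplismaParams
from .synthetic import SyntheticConfig, generate_split

BENCH_GRID_STEP = 1.0
BENCH_SMOOTHING = SmoothingParams(poly_degree=2, window=21)
BENCH_SIMPLISMA = SimplismaParams(alpha_percent=0.01, rs_threshold=2e-5)


def benchmark_synthetic(seed: int, *, saturation: float | None = 1.5,
                        noise_sd: float | None = None, linear: bool = False) -> SyntheticConfig:
    """Synthetic study conditions for one benchmark replicate."""
    kwargs = dict(wavelength_step=BENCH_GRID_STEP, saturation_a_max=saturation, seed=seed)
    if linear:
        kwargs.update(noise_sd=0.0, baseline_sd=0.0, drift_sd=0.0,
                      wavelength_jitter_sd=0.0, saturation_a_max=None)
    elif noise_sd is not None:
        kwargs.update(noise_sd=noise_sd)
    return SyntheticConfig(**kwargs)


def benchmark_pipeline(wavelength_selection: bool = True) -> PipelineConfig:
    return PipelineConfig(
        simplisma=BENCH_SIMPLISMA,
        sweep_start=5,
        sweep_step=3,
        wavelength_selection=wavelength_selection,
        select_before_sizing=wavelength_selection,
    )


def run_replicate(seed: int, methods=("sgrc", "global"), *,
                  saturation: float | None = 1.5, noise_sd: float | None = None,
                  linear: bool = False, wavelength_selection: bool = True):
    """Generate one replicate, smooth, evaluate the given criteria.

    Returns the :class:`~localpls.pipeline.EvaluationReport`.
    """
    cfg = benchmark_synthetic(seed, saturation=saturation, noise_sd=noise_sd, linear=linear)
    cal, pred = generate_split(cfg)
    cal = sg_smooth(cal, BENCH_SMOOTHING)
    pred = sg_smooth(pred, BENCH_SMOOTHING)
    pipe = benchmark_pipeline(wavelength_selection=wavelength_selection)
    return evaluate(pred, cal, methods=methods, config=pipe)


def local_vs_global_study(seeds, **kwargs):
    """RMSEP arrays (n_seeds x n_analytes) for local S-GRC and global PLS."""
    local, global_ = [], []
    for seed in seeds:
        report = run_replicate(seed, methods=("sgrc", "global"), **kwargs)
        local.append(report.rmsep_table.loc["sgrc"].values)
        global_.append(report.rmsep_table.loc["global"].values)
    return np.asarray(local), np.asarray(global_)
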