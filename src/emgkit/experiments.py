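"""Benchmark experiments: architecture/learning-rate sweep and multi-day
training progression on the synthetic gesture benchmark.

These scripts reproduce, on synthetic data, the two empirical procedures the
interface was tuned with: a grid search over network depth, hidden width and
learning rate (selecting the architecture by mean test error over seeds), and
a day-over-day training progression scored by the NP index.  Human learning
is emulated in the generator by raising the recording SNR a fixed number of
decibels per simulated training day.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .control import clamp_error, progress_report
from .features import WindowConfig, featurize, training_set
from .mlp import init_model, train
from .synth import make_benchmark

__all__ = [
    "ExperimentConfig",
    "run_benchmark_once",
    "run_architecture_sweep",
    "run_training_progression",
]

log = logging.getLogger("emgkit")


@dataclass
class ExperimentConfig:
    """Benchmark defaults: 6 channels, 9 gestures, 200/100 ms windows,
    one hidden layer of 8 neurons (two trainable layers), eta = 0.01."""

    n_channels: int = 6
    n_gestures: int = 9
    window_ms: float = 200.0
    step_ms: float = 100.0
    sampling_rate: float = 1000.0
    trial_duration_ms: float = 2000.0
    snr_db: float = 20.0
    layers_grid: tuple[int, ...] = (2,)  # trainable weight layers
    hidden_grid: tuple[int, ...] = (8,)
    learning_rates: tuple[float, ...] = (0.01,)
    max_epochs: int = 5000
    patience: int = 50
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)

    def window_config(self) -> WindowConfig:
        return WindowConfig.from_ms(self.window_ms, self.step_ms, self.sampling_rate)


def _layer_sizes(config: ExperimentConfig, layers: int, hidden: int) -> list[int]:
    if layers < 1:
        raise ValueError("layers must be >= 1")
    return (
        [config.n_channels]
        + [hidden] * (layers - 1)
        + [config.n_gestures]
    )


def run_benchmark_once(
    config: ExperimentConfig,
    layers: int,
    hidden: int,
    learning_rate: float,
    seed: int,
    snr_db: float | None = None,
) -> dict:
    """Generate one train/test benchmark, train one network, score it."""
    train_rec, test_rec = make_benchmark(
        n_gestures=config.n_gestures,
        n_series=2,
        trial_duration_ms=config.trial_duration_ms,
        seed=seed,
        n_channels=config.n_channels,
        snr_db=config.snr_db if snr_db is None else snr_db,
        sampling_rate=config.sampling_rate,
    )
    wc = config.window_config()
    train_xy = training_set(featurize(train_rec, wc))
    test_xy = training_set(featurize(test_rec, wc))
    model = init_model(_layer_sizes(config, layers, hidden), seed=seed)
    run, fitted = train(
        model,
        train_xy,
        test_xy,
        learning_rate=learning_rate,
        max_epochs=config.max_epochs,
        patience=config.patience,
        seed=seed,
    )
    train_err, test_err = run.epoch_log[run.best_epoch - 1]
    log.info(
        "benchmark seed=%d layers=%d hidden=%d lr=%g: windows train=%d test=%d, "
        "epochs=%d (%s), train_err=%.4f test_err=%.4f",
        seed, layers, hidden, learning_rate, len(train_xy[1]), len(test_xy[1]),
        run.stopped_at, run.stop_reason, train_err, test_err,
    )
    return {
        "train_error": train_err,
        "test_error": test_err,
        "epochs": run.stopped_at,
        "n_test_windows": len(test_xy[1]),
        "model": fitted,
        "run": run,
    }


def run_architecture_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """Grid over (layers, hidden, learning rate), mean +- sd across seeds.

    Infeasible cells (hidden < 1 with more than one trainable layer) are
    skipped with a warning.  The row minimizing mean test error is flagged
    in the ``best`` column.
    """
    rows = []
    for layers in config.layers_grid:
        for hidden in config.hidden_grid:
            if layers > 1 and hidden < 1:
                warnings.warn(
                    f"skipping infeasible cell layers={layers}, hidden={hidden}",
                    stacklevel=2,
                )
                continue
            for lr in config.learning_rates:
                res = [
                    run_benchmark_once(config, layers, hidden, lr, seed)
                    for seed in config.seeds
                ]
                tr = np.array([r["train_error"] for r in res])
                te = np.array([r["test_error"] for r in res])
                ep = np.array([r["epochs"] for r in res])
                rows.append(
                    {
                        "layers": layers,
                        "hidden": hidden if layers > 1 else 0,
                        "learning_rate": lr,
                        "train_error_mean": tr.mean(),
                        "train_error_sd": tr.std(ddof=1) if len(tr) > 1 else 0.0,
                        "test_error_mean": te.mean(),
                        "test_error_sd": te.std(ddof=1) if len(te) > 1 else 0.0,
                        "epochs_mean": ep.mean(),
                    }
                )
    if not rows:
        raise ValueError("sweep grid is empty")
    table = pd.DataFrame(rows)
    table["best"] = False
    table.loc[table["test_error_mean"].idxmin(), "best"] = True
    return table


def run_training_progression(
    config: ExperimentConfig,
    n_days: int,
    per_day_effect_db: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated multi-day training scored by the NP index.

    Day d is recorded at ``snr_db + per_day_effect_db * (d - 1)``: the
    generator's SNR stands in for the subject's growing gesture consistency.
    The same benchmark seed is reused each day so that a zero effect yields
    identical sessions (NP exactly 0).  Zero-error days are clamped to half
    of one misclassified window before taking the log-ratio.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    layers = config.layers_grid[0]
    hidden = config.hidden_grid[0]
    lr = config.learning_rates[0]
    errors = []
    for day in range(1, n_days + 1):
        snr = config.snr_db + per_day_effect_db * (day - 1)
        res = run_benchmark_once(config, layers, hidden, lr, seed, snr_db=snr)
        errors.append(clamp_error(res["test_error"], res["n_test_windows"]))
    progress = progress_report(errors)
    return pd.DataFrame(
        {
            "day": np.arange(1, n_days + 1),
            "test_error": progress.errors,
            "np": progress.np_values,
        }
    )
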