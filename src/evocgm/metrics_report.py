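"""Error metrics, unit conversions and the two-method comparison summary.

MSE is the fitness and evaluation criterion throughout::

    MSE = sum_i (y_i - yhat_i)^2 / n        [(mmol/L)^2]

RMSE = sqrt(MSE) restates errors in glucose units (mmol/L).  The summary
compares the evolved and backprop sweeps: absolute and relative drops in
MSE and RMSE, and the relative reduction in the selected window size.

Reporting conventions: MSE to 3 dp, RMSE to 4 dp, percentages to 1 dp.
Headline improvements are computed from the *rounded* best MSEs (so they
match what a reader recomputes from a printed table); the unrounded
variants are carried alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np


class MetricsError(ValueError):
    """Invalid metric inputs."""


def mse(actual, predicted) -> float:
    """Mean squared error between two equally long vectors."""
    y = np.asarray(actual, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise MetricsError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise MetricsError("cannot compute MSE of empty vectors")
    return float(np.mean((y - yhat) ** 2))


def rmse_from_mse(value: float) -> float:
    """Square root of an MSE, back in mmol/L."""
    if value < 0:
        raise MetricsError("MSE cannot be negative")
    return float(np.sqrt(value))


def relative_improvement(new: float, reference: float) -> float:
    """Percent reduction of ``new`` relative to ``reference``."""
    if reference <= 0:
        raise MetricsError("reference must be positive")
    return 100.0 * (reference - new) / reference


@dataclass(frozen=True)
class ComparisonSummary:
    """Head-to-head comparison of the evolved and backprop sweeps."""

    evolved_window: int
    evolved_val_mse: float
    evolved_test_mse: float
    baseline_window: int
    baseline_val_mse: float
    baseline_test_mse: float
    # Headline numbers from MSEs rounded to 3 dp (printed-table arithmetic).
    mse_drop: float
    mse_improvement_pct: float
    evolved_rmse: float
    baseline_rmse: float
    rmse_drop: float
    rmse_improvement_pct: float
    window_reduction_pct: float
    # Same quantities from the unrounded MSEs.
    mse_drop_unrounded: float
    mse_improvement_pct_unrounded: float
    rmse_drop_unrounded: float
    rmse_improvement_pct_unrounded: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def summarize_comparison(evolved, baseline) -> ComparisonSummary:
    """Build the comparison from two :class:`~evocgm.evolution.SweepReport`.

    Both sweeps must cover the same window sizes (fairness requires the
    same candidate set and splits).  The comparison uses each method's
    best *validation* MSE — the quantity the window was selected on —
    with test MSEs reported alongside.
    """
    ev_windows = [r.window_size for r in evolved.rows]
    bp_windows = [r.window_size for r in baseline.rows]
    if ev_windows != bp_windows:
        raise MetricsError(
            f"window ranges differ: {ev_windows} vs {bp_windows}"
        )

    ev_mse_r = round(evolved.best_val_mse, 3)
    bp_mse_r = round(baseline.best_val_mse, 3)
    ev_rmse = round(rmse_from_mse(ev_mse_r), 4)
    bp_rmse = round(rmse_from_mse(bp_mse_r), 4)

    return ComparisonSummary(
        evolved_window=evolved.selected_window,
        evolved_val_mse=evolved.best_val_mse,
        evolved_test_mse=evolved.test_mse,
        baseline_window=baseline.selected_window,
        baseline_val_mse=baseline.best_val_mse,
        baseline_test_mse=baseline.test_mse,
        mse_drop=round(bp_mse_r - ev_mse_r, 3),
        mse_improvement_pct=round(relative_improvement(ev_mse_r, bp_mse_r), 1),
        evolved_rmse=ev_rmse,
        baseline_rmse=bp_rmse,
        rmse_drop=round(bp_rmse - ev_rmse, 4),
        rmse_improvement_pct=round(relative_improvement(ev_rmse, bp_rmse), 1),
        window_reduction_pct=round(
            relative_improvement(evolved.selected_window, baseline.selected_window), 1
        ),
        mse_drop_unrounded=baseline.best_val_mse - evolved.best_val_mse,
        mse_improvement_pct_unrounded=relative_improvement(
            evolved.best_val_mse, baseline.best_val_mse
        ),
        rmse_drop_unrounded=rmse_from_mse(baseline.best_val_mse)
        - rmse_from_mse(evolved.best_val_mse),
        rmse_improvement_pct_unrounded=relative_improvement(
            rmse_from_mse(evolved.best_val_mse), rmse_from_mse(baseline.best_val_mse)
        ),
    )


def sweep_to_csv(report, path) -> None:
    """Write one sweep as CSV (window_size, validation_mse) plus footer rows."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("window_size,validation_mse\n")
        for row in report.rows:
            fh.write(f"{row.window_size},{row.val_mse!r}\n")
        fh.write(f"# selected_window,{report.selected_window}\n")
        fh.write(f"# test_mse,{report.test_mse!r}\n")


def history_to_csv(history, path) -> None:
    """Write an evolution history as CSV, one row per generation."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("generation,best_train_mse,best_val_mse,mean_val_mse\n")
        for r in history.records:
            fh.write(
                f"{r.generation},{r.best_train_mse!r},"
                f"{r.best_val_mse!r},{r.mean_val_mse!r}\n"
            )


def plot_forecast(actual, predicted, path, title="One-step CGM forecast") -> None:
    """Line plot of actual vs predicted glucose over the series."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    ax.plot(np.asarray(actual), label="actual", lw=1.0)
    ax.plot(np.asarray(predicted), label="predicted", lw=1.0, alpha=0.8)
    ax.set_xlabel("reading index (5-min steps)")
    ax.set_ylabel("glucose (mmol/L)")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_history(history, path, title="Evolution of prediction error") -> None:
    """Train/validation error against generation (early-stopping view)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    gens = [r.generation for r in history.records]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(gens, [r.best_train_mse for r in history.records], label="best train MSE")
    ax.plot(gens, [r.best_val_mse for r in history.records], label="best val MSE")
    ax.plot(gens, [r.mean_val_mse for r in history.records],
            label="mean val MSE", ls="--")
    ax.set_xlabel("generation")
    ax.set_ylabel("MSE ((mmol/L)^2)")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
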