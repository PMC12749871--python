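"""End-to-end experiment runner: data → preprocessing → sweeps → report.

Ties the pipeline together exactly as the study protocol runs it: obtain
a trace (read a CSV or simulate one), interpolate short gaps, segment,
sweep window sizes with both the evolved and the backprop-trained
network on *identical* splits, and summarise the comparison.  One global
seed deterministically derives every per-stage seed, so any stage can be
rerun in isolation and a full rerun is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cgm_io import (
    DEFAULT_JITTER_TOL_S,
    DEFAULT_MAX_GAP_S,
    CGMSeries,
    interpolate_gaps,
    read_cgm_csv,
    write_cgm_csv,
)
from .evolution import (
    EvolutionConfig,
    build_window_datasets,
    sweep_window_sizes,
    _derived_seed,
)
from .metrics_report import (
    ComparisonSummary,
    summarize_comparison,
    sweep_to_csv,
)
from .synthetic_data import SimParams, generate_cgm, inject_artifacts
from .windowing import SplitSpec

logger = logging.getLogger("evocgm")


class ConfigError(ValueError):
    """Invalid experiment configuration (message names the field)."""


@dataclass(frozen=True)
class BackpropConfig:
    """Baseline trainer settings (full-batch gradient descent)."""

    lr: float = 0.01
    max_epochs: int = 500
    patience: int = 3

    def validate(self) -> None:
        if self.lr < 0:
            raise ConfigError("backprop.lr must be >= 0")
        if self.max_epochs < 1:
            raise ConfigError("backprop.max_epochs must be >= 1")
        if self.patience < 1:
            raise ConfigError("backprop.patience must be >= 1")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one full comparison experiment."""

    data_path: str | None = None
    sim_params: SimParams | None = None
    split: SplitSpec = field(default_factory=SplitSpec)
    evolution: EvolutionConfig = field(default_factory=EvolutionConfig)
    backprop: BackpropConfig = field(default_factory=BackpropConfig)
    outdir: str = "evocgm_run"
    seed: int = 0
    max_gap_s: float = DEFAULT_MAX_GAP_S
    jitter_tol_s: float = DEFAULT_JITTER_TOL_S

    def validate(self) -> None:
        if (self.data_path is None) == (self.sim_params is None):
            raise ConfigError(
                "exactly one data source required: set data_path or sim_params"
            )
        self.split.validate()
        self.evolution.validate()
        self.backprop.validate()
        if self.sim_params is not None:
            self.sim_params.validate()

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "sim_params" in d and d["sim_params"] is not None:
            d["sim_params"] = SimParams.from_dict(d["sim_params"])
        if "split" in d:
            d["split"] = SplitSpec(**d["split"])
        if "evolution" in d:
            ev = dict(d["evolution"])
            for key in ("hidden_layers", "window_range", "crossover_coefficients"):
                if key in ev:
                    ev[key] = tuple(ev[key])
            d["evolution"] = EvolutionConfig(**ev)
        if "backprop" in d:
            d["backprop"] = BackpropConfig(**d["backprop"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _dataset_digest(datasets: dict) -> str:
    """SHA-256 over every split's bytes, in window order."""
    h = hashlib.sha256()
    for w in sorted(datasets):
        for ds in datasets[w]:
            h.update(np.ascontiguousarray(ds.inputs).tobytes())
            h.update(np.ascontiguousarray(ds.targets).tobytes())
    return h.hexdigest()


def load_or_simulate(config: ExperimentConfig) -> CGMSeries:
    """Resolve the configured data source into a raw trace."""
    if config.data_path is not None:
        logger.info("reading CGM trace from %s", config.data_path)
        return read_cgm_csv(config.data_path)
    params = config.sim_params
    sim_seed = _derived_seed(config.seed, 101)
    params = SimParams(**{**params.to_dict(), "seed": sim_seed})
    logger.info(
        "simulating %.2f-day trace (seed %d)", params.duration_days, sim_seed
    )
    clean = generate_cgm(params)
    return inject_artifacts(
        clean, params.missing_rate, params.jitter_fraction,
        seed=_derived_seed(config.seed, 102),
    )


def run_experiment(config: ExperimentConfig) -> ComparisonSummary:
    """Run the full protocol and write the report files.

    Writes to ``config.outdir``: the (possibly simulated) trace, one
    sweep CSV per method, the per-generation history of the selected
    evolved window, and ``summary.json``.  Both methods are trained on
    byte-identical splits (asserted by hashing the datasets).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    series = load_or_simulate(config)
    if config.sim_params is not None:
        write_cgm_csv(series, outdir / "trace.csv")
    filled = interpolate_gaps(
        series, max_gap=config.max_gap_s, jitter_tol=config.jitter_tol_s
    )
    logger.info(
        "trace: %d readings (%d after gap interpolation)", len(series), len(filled)
    )

    datasets = build_window_datasets(
        filled, config.evolution.window_range, config.split,
        jitter_tol=config.jitter_tol_s,
    )
    digest = _dataset_digest(datasets)
    logger.info("split digest %s", digest[:16])

    cfg = EvolutionConfig(**{
        **config.evolution.__dict__, "seed": _derived_seed(config.seed, 201)
    })
    bp = {
        "lr": config.backprop.lr,
        "max_epochs": config.backprop.max_epochs,
        "patience": config.backprop.patience,
    }

    reports = {}
    for method in ("evolve", "backprop"):
        # Identical datasets object for both methods: the fairness contract.
        assert _dataset_digest(datasets) == digest
        logger.info("running %s sweep over windows %s", method, cfg.window_range)
        reports[method] = sweep_window_sizes(
            filled, cfg, config.split, method=method,
            backprop_params=bp, datasets=datasets,
        )
        sweep_to_csv(reports[method], outdir / f"sweep_{method}.csv")
        logger.info(
            "%s: selected window %d (val MSE %.4f, test MSE %.4f)",
            method, reports[method].selected_window,
            reports[method].best_val_mse, reports[method].test_mse,
        )

    summary = summarize_comparison(reports["evolve"], reports["backprop"])
    payload = dict(summary.to_dict())
    payload["seed"] = config.seed
    payload["split_digest"] = digest
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if reports["evolve"].selected_model is not None:
        reports["evolve"].selected_model.save(outdir / "model_evolved.json")
    return summary
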