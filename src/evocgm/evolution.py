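"""Genetic algorithm evolving network weights, plus the window-size sweep.

The GA is deliberately light on hyper-parameters.  Each generation every
one of ``population_size`` families is formed by roulette-wheel-selecting
two distinct parents on scaled *training* fitness (``1 / (mse + eps)``).
A family produces four children by averaging crossover with four fixed
coefficients; the last two children are additionally mutated by bounded
uniform noise.  The six family members (parents first) compete and the
lowest-training-MSE individual survives, so the population size is
constant and each family can never regress below its better parent
("family elitism").  There are no separate crossover/mutation/elitism
probabilities to tune.

Validation data plays two roles, kept strictly apart from selection:
early stopping (halt when the population-mean validation MSE rises for
``patience`` consecutive generations) and final model choice (the
minimum-validation-MSE individual of the final generation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .cgm_io import CGMSeries, DEFAULT_JITTER_TOL_S
from .neuralnet import (
    DEFAULT_HIDDEN,
    DEFAULT_INIT_SCALE,
    DivergenceError,
    Genotype,
    Topology,
    backprop_train,
    init_genotype,
    mse_of,
)
from .windowing import (
    DEFAULT_WINDOW_RANGE,
    SplitSpec,
    WindowDataset,
    make_windows,
    split_chronological,
)

FITNESS_EPS = 1e-8


class EvolutionError(ValueError):
    """Invalid GA configuration or degenerate inputs."""


@dataclass(frozen=True)
class EvolutionConfig:
    """Settings of the evolutionary run.

    Defaults follow the study protocol: 200 generations, population 100,
    maximum mutation 0.1, hidden architecture [5, 5, 5], window sizes 3
    through 10, early-stopping patience 3.
    """

    population_size: int = 100
    generations: int = 200
    max_mutation: float = 0.1
    hidden_layers: tuple[int, ...] = DEFAULT_HIDDEN
    window_range: tuple[int, int] = DEFAULT_WINDOW_RANGE
    patience: int = 3
    init_scale: float = DEFAULT_INIT_SCALE
    seed: int = 0
    crossover_coefficients: tuple[float, float, float, float] = (0.2, 0.4, 0.6, 0.8)
    hidden_activation: str = "relu"
    output_activation: str = "identity"
    bias_placement: str = "post_activation"
    early_stop_statistic: str = "population_mean"  # or "best"
    early_stop_threshold: float = 0.0

    def validate(self) -> None:
        if self.population_size < 2:
            raise EvolutionError("population_size must be >= 2")
        if self.generations < 1:
            raise EvolutionError("generations must be >= 1")
        if self.max_mutation < 0:
            raise EvolutionError("max_mutation must be >= 0")
        if self.patience < 1:
            raise EvolutionError("patience must be >= 1")
        if len(self.crossover_coefficients) != 4 or any(
            not 0.0 <= a <= 1.0 for a in self.crossover_coefficients
        ):
            raise EvolutionError("need 4 crossover coefficients in [0, 1]")
        if self.early_stop_statistic not in ("population_mean", "best"):
            raise EvolutionError(
                f"unknown early_stop_statistic {self.early_stop_statistic!r}"
            )

    def topology_for(self, window_size: int) -> Topology:
        return Topology.for_window(
            window_size,
            hidden=self.hidden_layers,
            hidden_activation=self.hidden_activation,
            output_activation=self.output_activation,
            bias_placement=self.bias_placement,
        )


@dataclass(frozen=True)
class GenerationRecord:
    """Summary of one generation for reporting and early stopping."""

    generation: int
    best_train_mse: float
    best_val_mse: float
    mean_val_mse: float


@dataclass
class EvolutionHistory:
    """Per-generation records plus the archived best-so-far champion.

    The champion (lowest validation MSE seen in any generation) is kept
    for reporting only; it is never re-injected into the population, so
    convergence rests on family elitism alone.
    """

    records: list[GenerationRecord] = field(default_factory=list)
    stop_reason: str = ""
    champion: Genotype | None = None
    champion_val_mse: float = np.inf

    @property
    def generations_run(self) -> int:
        return len(self.records)


class EarlyStopMonitor:
    """Patience rule: stop after `patience` consecutive strict increases.

    An increase counts when the monitored statistic exceeds the previous
    generation's value by more than ``threshold`` (default 0, i.e. any
    strict increase).
    """

    def __init__(self, patience: int, threshold: float = 0.0):
        if patience < 1:
            raise EvolutionError("patience must be >= 1")
        self.patience = patience
        self.threshold = threshold
        self._prev = np.inf
        self._streak = 0

    def update(self, value: float) -> bool:
        """Record this generation's statistic; True means halt now."""
        if value > self._prev + self.threshold:
            self._streak += 1
        else:
            self._streak = 0
        self._prev = value
        return self._streak >= self.patience


# ---------------------------------------------------------------------------
# GA primitives
# ---------------------------------------------------------------------------

def scale_fitness(mses: np.ndarray, eps: float = FITNESS_EPS) -> np.ndarray:
    """Map errors to positive fitness: ``1 / (mse + eps)``.

    Strictly decreasing in MSE, so minimising error maximises fitness.
    """
    mses = np.asarray(mses, dtype=float)
    if not np.isfinite(mses).all():
        raise EvolutionError("non-finite MSE in fitness scaling")
    if (mses < 0).any():
        raise EvolutionError("negative MSE in fitness scaling")
    return 1.0 / (mses + eps)


def roulette_select(
    fitness: np.ndarray, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``count`` indices with replacement, P(i) ∝ fitness_i.

    Implements the cumulative-distribution wheel; an all-zero fitness
    vector falls back to uniform draws.
    """
    fitness = np.asarray(fitness, dtype=float)
    if (fitness < 0).any():
        raise EvolutionError("fitness must be non-negative")
    total = fitness.sum()
    if total <= 0:
        p = np.full(len(fitness), 1.0 / len(fitness))
    else:
        p = fitness / total
    return rng.choice(len(fitness), size=count, replace=True, p=p)


def crossover(p1: Genotype, p2: Genotype, alpha: float) -> Genotype:
    """Averaging crossover: every child matrix is ``alpha*p1 + (1-alpha)*p2``."""
    if p1.topology != p2.topology:
        raise EvolutionError("cannot cross over genotypes of different topology")
    return Genotype(
        p1.topology,
        [alpha * W1 + (1.0 - alpha) * W2 for W1, W2 in zip(p1.weights, p2.weights)],
        [alpha * b1 + (1.0 - alpha) * b2 for b1, b2 in zip(p1.biases, p2.biases)],
    )


def mutate(
    g: Genotype, max_mutation: float, rng: np.random.Generator
) -> Genotype:
    """Perturb every entry by an independent U(-max_mutation, max_mutation)."""
    if max_mutation < 0:
        raise EvolutionError("max_mutation must be >= 0")
    return Genotype(
        g.topology,
        [W + rng.uniform(-max_mutation, max_mutation, W.shape) for W in g.weights],
        [b + rng.uniform(-max_mutation, max_mutation, b.shape) for b in g.biases],
    )


def reproduce_family(
    p1: Genotype,
    p2: Genotype,
    train: WindowDataset,
    cfg: EvolutionConfig,
    rng: np.random.Generator,
    parent_mses: tuple[float, float] | None = None,
) -> tuple[Genotype, float]:
    """One family: 4 crossover children (last 2 mutated), best of 6 survives.

    The pool is ordered parents first, then children; ties in training
    MSE go to the earliest pool member, so a child must strictly beat
    both parents to displace them.  Returns the survivor and its training
    MSE.
    """
    children = [crossover(p1, p2, a) for a in cfg.crossover_coefficients]
    children[2] = mutate(children[2], cfg.max_mutation, rng)
    children[3] = mutate(children[3], cfg.max_mutation, rng)

    pool = [p1, p2] + children
    if parent_mses is None:
        parent_mses = (mse_of(p1, train), mse_of(p2, train))
    mses = list(parent_mses) + [mse_of(c, train) for c in children]
    best = int(np.argmin(mses))  # argmin takes the first minimum: parents win ties
    return pool[best], mses[best]


# ---------------------------------------------------------------------------
# Main evolutionary loop
# ---------------------------------------------------------------------------

def evolve(
    train: WindowDataset,
    val: WindowDataset,
    cfg: EvolutionConfig,
    rng: np.random.Generator | None = None,
) -> tuple[Genotype, EvolutionHistory]:
    """Evolve a population of networks on ``train``, early-stopped on ``val``.

    Returns the minimum-validation-MSE individual of the final generation
    together with the full per-generation history (which also archives
    the best-so-far champion).  Deterministic given ``cfg.seed`` (or an
    explicitly passed generator).
    """
    cfg.validate()
    if len(train) == 0 or len(val) == 0:
        raise EvolutionError("training and validation sets must be non-empty")
    if train.window_size != val.window_size:
        raise EvolutionError("train/val window sizes differ")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    topo = cfg.topology_for(train.window_size)
    pop = [
        init_genotype(topo, scale=cfg.init_scale, rng=rng)
        for _ in range(cfg.population_size)
    ]
    train_mses = np.array([mse_of(g, train) for g in pop])

    history = EvolutionHistory()
    monitor = EarlyStopMonitor(cfg.patience, cfg.early_stop_threshold)
    val_mses = np.empty(cfg.population_size)

    for gen in range(cfg.generations):
        fitness = scale_fitness(train_mses)
        new_pop: list[Genotype] = []
        new_mses = np.empty(cfg.population_size)
        for fam in range(cfg.population_size):
            i = int(roulette_select(fitness, 1, rng)[0])
            j = i
            while j == i:
                j = int(roulette_select(fitness, 1, rng)[0])
            survivor, s_mse = reproduce_family(
                pop[i], pop[j], train, cfg, rng,
                parent_mses=(float(train_mses[i]), float(train_mses[j])),
            )
            new_pop.append(survivor)
            new_mses[fam] = s_mse
        pop, train_mses = new_pop, new_mses

        for k, g in enumerate(pop):
            val_mses[k] = mse_of(g, val)
        if not np.isfinite(val_mses).all():
            raise EvolutionError(f"non-finite validation MSE at generation {gen}")

        best_val_idx = int(np.argmin(val_mses))
        record = GenerationRecord(
            generation=gen,
            best_train_mse=float(train_mses.min()),
            best_val_mse=float(val_mses[best_val_idx]),
            mean_val_mse=float(val_mses.mean()),
        )
        history.records.append(record)
        if record.best_val_mse < history.champion_val_mse:
            history.champion_val_mse = record.best_val_mse
            history.champion = pop[best_val_idx].copy()

        statistic = (
            record.mean_val_mse
            if cfg.early_stop_statistic == "population_mean"
            else record.best_val_mse
        )
        if monitor.update(statistic):
            history.stop_reason = "early_stop"
            break
    else:
        history.stop_reason = "max_generations"

    best = pop[int(np.argmin(val_mses))]
    return best, history


# ---------------------------------------------------------------------------
# Window-size sweep
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepRow:
    """Best validation MSE achieved at one window size."""

    window_size: int
    val_mse: float
    model: Genotype | None = field(compare=False, default=None)
    diverged: bool = False


@dataclass
class SweepReport:
    """Per-window results, the selected model and its single test score."""

    method: str
    rows: list[SweepRow]
    selected_window: int
    best_val_mse: float
    test_mse: float
    selected_model: Genotype | None = None

    def val_mse_of(self, window_size: int) -> float:
        for row in self.rows:
            if row.window_size == window_size:
                return row.val_mse
        raise KeyError(window_size)


def _derived_seed(base_seed: int, *keys: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence([int(base_seed), *[int(k) for k in keys]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def build_window_datasets(
    series: CGMSeries,
    window_range: tuple[int, int] = DEFAULT_WINDOW_RANGE,
    split: SplitSpec = SplitSpec(),
    jitter_tol: float = DEFAULT_JITTER_TOL_S,
) -> dict[int, tuple[WindowDataset, WindowDataset, WindowDataset]]:
    """Pre-build identical train/val/test datasets for every window size.

    Sharing one datasets dict between the evolved and backprop sweeps
    guarantees both methods see byte-identical splits.
    """
    lo, hi = window_range
    return {
        w: split_chronological(
            make_windows(series, w, window_range=window_range, jitter_tol=jitter_tol),
            split,
        )
        for w in range(lo, hi + 1)
    }


def sweep_window_sizes(
    series: CGMSeries,
    cfg: EvolutionConfig,
    split: SplitSpec = SplitSpec(),
    method: str = "evolve",
    backprop_params: dict | None = None,
    datasets: dict | None = None,
    replicates: int = 1,
) -> SweepReport:
    """Run the training method at every window size and pick the best.

    For each window size the datasets are rebuilt, the method trained
    (``replicates`` independent runs; the best validation score is kept),
    and the best validation MSE recorded.  The window with the minimum
    validation MSE is selected and its model evaluated once on the test
    set.  A diverged backprop run is recorded as an infinite-MSE row
    rather than aborting the sweep.
    """
    cfg.validate()
    if method not in ("evolve", "backprop"):
        raise EvolutionError(f"unknown sweep method {method!r}")
    if replicates < 1:
        raise EvolutionError("replicates must be >= 1")
    bp = {"lr": 0.01, "max_epochs": 500, "patience": cfg.patience}
    if backprop_params:
        bp.update(backprop_params)
    if datasets is None:
        datasets = build_window_datasets(series, cfg.window_range, split)

    rows: list[SweepRow] = []
    lo, hi = cfg.window_range
    for w in range(lo, hi + 1):
        train, val, _ = datasets[w]
        best_val = np.inf
        best_model: Genotype | None = None
        diverged = False
        for rep in range(replicates):
            run_seed = _derived_seed(cfg.seed, w, rep, 0 if method == "evolve" else 1)
            if method == "evolve":
                model, _hist = evolve(train, val, dc_replace(cfg, seed=run_seed))
                v = mse_of(model, val)
            else:
                g0 = init_genotype(
                    cfg.topology_for(w), scale=cfg.init_scale, seed=run_seed
                )
                try:
                    model, _hist = backprop_train(
                        g0, train, val,
                        lr=bp["lr"], max_epochs=bp["max_epochs"],
                        patience=bp["patience"],
                    )
                    v = mse_of(model, val)
                except DivergenceError:
                    model, v, diverged = None, np.inf, True
            if v < best_val:
                best_val, best_model = v, model
        rows.append(
            SweepRow(w, float(best_val), best_model, diverged and best_model is None)
        )

    finite = [r for r in rows if np.isfinite(r.val_mse)]
    if not finite:
        raise EvolutionError("every window size diverged; no model to select")
    selected = min(finite, key=lambda r: r.val_mse)
    _, _, test = datasets[selected.window_size]
    test_mse = mse_of(selected.model, test)
    return SweepReport(
        method=method,
        rows=rows,
        selected_window=selected.window_size,
        best_val_mse=selected.val_mse,
        test_mse=float(test_mse),
        selected_model=selected.model,
    )
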