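import numpy as np
import pytest

from evocgm import (
    EvolutionConfig,
    SplitSpec,
    Topology,
    WindowDataset,
    crossover,
    evolve,
    init_genotype,
    make_windows,
    mse_of,
    mutate,
    reproduce_family,
    roulette_select,
    scale_fitness,
    split_chronological,
    sweep_window_sizes,
)
from evocgm.evolution import EarlyStopMonitor, EvolutionError

from conftest import make_series


def small_dataset(rng, n=40, w=3):
    X = rng.uniform(4, 10, (n, w))
    y = X.mean(axis=1) + rng.normal(0, 0.2, n)
    return WindowDataset(X, y, w)


class TestScaleFitness:
    def test_monotone_decreasing_in_mse(self):
        f = scale_fitness(np.array([0.1, 0.3]))
        assert f[0] > f[1]

    def test_equal_mses_equal_fitness(self):
        f = scale_fitness(np.array([0.2, 0.2]))
        assert f[0] == f[1]

    def test_zero_mse_finite(self):
        f = scale_fitness(np.array([0.0]))
        assert np.isfinite(f[0])
        assert f[0] == pytest.approx(1e8)

    def test_non_finite_rejected(self):
        with pytest.raises(EvolutionError):
            scale_fitness(np.array([np.nan]))


class TestRouletteSelect:
    def test_degenerate_mass(self, rng):
        sel = roulette_select(np.array([1.0, 0.0, 0.0]), 50, rng)
        assert (sel == 0).all()

    def test_even_mass_is_near_half(self, rng):
        sel = roulette_select(np.array([1.0, 1.0]), 10_000, rng)
        assert abs(np.mean(sel == 0) - 0.5) < 0.015

    def test_all_zero_falls_back_to_uniform(self, rng):
        sel = roulette_select(np.array([0.0, 0.0]), 2_000, rng)
        assert 0.4 < np.mean(sel == 0) < 0.6

    def test_negative_fitness_rejected(self, rng):
        with pytest.raises(EvolutionError):
            roulette_select(np.array([1.0, -0.1]), 1, rng)


class TestCrossoverAndMutate:
    def setup_method(self):
        self.t = Topology.for_window(3)
        self.p1 = init_genotype(self.t, seed=1)
        self.p2 = init_genotype(self.t, seed=2)

    def test_alpha_one_is_first_parent(self):
        c = crossover(self.p1, self.p2, 1.0)
        for W, Wp in zip(c.weights, self.p1.weights):
            np.testing.assert_array_equal(W, Wp)

    def test_midpoint(self):
        c = crossover(self.p1, self.p2, 0.5)
        np.testing.assert_allclose(
            c.weights[0], (self.p1.weights[0] + self.p2.weights[0]) / 2
        )

    def test_identical_parents_fixed_point(self):
        c = crossover(self.p1, self.p1, 0.37)
        for W, Wp in zip(c.weights, self.p1.weights):
            np.testing.assert_allclose(W, Wp)

    def test_topology_mismatch_rejected(self):
        other = init_genotype(Topology.for_window(4), seed=3)
        with pytest.raises(EvolutionError):
            crossover(self.p1, other, 0.5)

    def test_mutation_bounded_and_out_of_place(self, rng):
        m = mutate(self.p1, 0.1, rng)
        for W, Wp in zip(m.weights, self.p1.weights):
            assert np.abs(W - Wp).max() <= 0.1
            assert not np.shares_memory(W, Wp)
        for b, bp in zip(m.biases, self.p1.biases):
            assert np.abs(b - bp).max() <= 0.1

    def test_zero_mutation_identity(self, rng):
        m = mutate(self.p1, 0.0, rng)
        for W, Wp in zip(m.weights, self.p1.weights):
            np.testing.assert_array_equal(W, Wp)

    def test_mutation_deterministic_per_seed(self):
        a = mutate(self.p1, 0.1, np.random.default_rng(5))
        b = mutate(self.p1, 0.1, np.random.default_rng(5))
        for Wa, Wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(Wa, Wb)


class TestReproduceFamily:
    def test_survivor_beats_both_parents(self, rng):
        train = small_dataset(rng)
        cfg = EvolutionConfig(population_size=2, generations=1)
        p1 = init_genotype(Topology.for_window(3), seed=1)
        p2 = init_genotype(Topology.for_window(3), seed=2)
        surv, s_mse = reproduce_family(p1, p2, train, cfg, rng)
        assert s_mse <= min(mse_of(p1, train), mse_of(p2, train))
        assert s_mse == pytest.approx(mse_of(surv, train))

    def test_identical_parents_no_mutation_survive_unchanged(self, rng):
        train = small_dataset(rng)
        cfg = EvolutionConfig(
            population_size=2, generations=1, max_mutation=0.0
        )
        p = init_genotype(Topology.for_window(3), seed=1)
        surv, _ = reproduce_family(p, p.copy(), train, cfg, rng)
        for W, Wp in zip(surv.weights, p.weights):
            np.testing.assert_allclose(W, Wp)


class TestEarlyStopMonitor:
    def test_three_consecutive_increases_halt(self):
        m = EarlyStopMonitor(patience=3)
        vals = [1.0, 0.9, 0.91, 0.92, 0.93]
        stops = [m.update(v) for v in vals]
        assert stops == [False, False, False, False, True]

    def test_streak_resets_on_decrease(self):
        m = EarlyStopMonitor(patience=3)
        vals = [1.0, 1.1, 1.2, 1.0, 1.1, 1.2, 1.3]
        stops = [m.update(v) for v in vals]
        assert stops == [False, False, False, False, False, False, True]

    def test_plateau_does_not_count(self):
        m = EarlyStopMonitor(patience=2)
        assert [m.update(v) for v in [1.0, 1.0, 1.0, 1.0]] == [False] * 4


class TestEvolve:
    def test_deterministic_history(self, rng):
        train = small_dataset(rng, 60)
        val = small_dataset(rng, 20)
        cfg = EvolutionConfig(population_size=8, generations=10, seed=42)
        _, h1 = evolve(train, val, cfg)
        _, h2 = evolve(train, val, cfg)
        assert h1.records == h2.records
        assert h1.stop_reason == h2.stop_reason

    def test_population_improves_and_history_complete(self, day_trace):
        ds = make_windows(day_trace, 3)
        tr, va, _ = split_chronological(ds)
        cfg = EvolutionConfig(population_size=12, generations=15, seed=0)
        best, hist = evolve(tr, va, cfg)
        assert 1 <= hist.generations_run <= 15
        assert hist.stop_reason in ("early_stop", "max_generations")
        # champion archive holds the best validation MSE ever seen
        assert hist.champion_val_mse == pytest.approx(
            min(r.best_val_mse for r in hist.records)
        )
        assert mse_of(best, va) == pytest.approx(hist.records[-1].best_val_mse)
        # evolution improved on the initial generation's champion
        assert hist.records[-1].best_train_mse <= hist.records[0].best_train_mse

    def test_beats_constant_mean_predictor(self, day_trace):
        ds = make_windows(day_trace, 3)
        tr, va, te = split_chronological(ds)
        cfg = EvolutionConfig(population_size=15, generations=25, seed=1)
        best, _ = evolve(tr, va, cfg)
        const_mse = float(np.mean((te.targets - tr.targets.mean()) ** 2))
        assert mse_of(best, te) <= const_mse

    def test_degenerate_config_rejected(self, rng):
        train = small_dataset(rng)
        with pytest.raises(EvolutionError):
            evolve(train, train, EvolutionConfig(population_size=1))


class TestSweep:
    def test_report_shape_and_selection(self, day_trace):
        cfg = EvolutionConfig(
            population_size=6, generations=5, window_range=(3, 5), seed=2
        )
        report = sweep_window_sizes(day_trace, cfg, SplitSpec())
        assert [r.window_size for r in report.rows] == [3, 4, 5]
        best_row = min(report.rows, key=lambda r: r.val_mse)
        assert report.selected_window == best_row.window_size
        assert report.best_val_mse == best_row.val_mse
        assert np.isfinite(report.test_mse)

    def test_backprop_method_runs(self, day_trace):
        cfg = EvolutionConfig(window_range=(3, 4), seed=3)
        report = sweep_window_sizes(
            day_trace, cfg, SplitSpec(), method="backprop",
            backprop_params={"max_epochs": 50},
        )
        assert len(report.rows) == 2
        assert report.method == "backprop"

    def test_unknown_method_rejected(self, day_trace):
        with pytest.raises(EvolutionError):
            sweep_window_sizes(
                day_trace, EvolutionConfig(), SplitSpec(), method="annealing"
            )
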