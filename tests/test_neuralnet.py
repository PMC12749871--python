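import numpy as np
import pytest

from evocgm import (
    Genotype,
    Topology,
    WindowDataset,
    backprop_train,
    forward_pass,
    init_genotype,
    mse_of,
)
from evocgm.neuralnet import DivergenceError, NeuralNetError


def forward_oracle(g: Genotype, X: np.ndarray) -> np.ndarray:
    """Independent per-neuron, per-observation loop implementation."""
    def act(name, v):
        if name == "relu":
            return max(v, 0.0)
        return v

    out = []
    L = g.topology.n_layers
    for row in X:
        a = list(row)
        for l in range(L):
            name = (
                g.topology.output_activation
                if l == L - 1
                else g.topology.hidden_activation
            )
            n_out = g.weights[l].shape[1]
            nxt = []
            for j in range(n_out):
                z = sum(a[k] * g.weights[l][k, j] for k in range(len(a)))
                if g.topology.bias_placement == "post_activation":
                    nxt.append(act(name, z) + g.biases[l][0, j])
                else:
                    nxt.append(act(name, z + g.biases[l][0, j]))
            a = nxt
        out.append(a[0])
    return np.array(out)


def random_dataset(rng, n, w):
    X = rng.uniform(3, 12, (n, w))
    y = rng.uniform(3, 12, n)
    return WindowDataset(X, y, w)


class TestTopologyAndInit:
    def test_default_parameter_count(self):
        g = init_genotype(Topology.for_window(3), seed=0)
        assert [W.shape for W in g.weights] == [(3, 5), (5, 5), (5, 5), (5, 1)]
        assert [b.shape for b in g.biases] == [(1, 5)] * 3 + [(1, 1)]
        assert g.n_params == 86

    def test_init_deterministic_and_bounded(self):
        t = Topology.for_window(4)
        a = init_genotype(t, scale=0.5, seed=7)
        b = init_genotype(t, scale=0.5, seed=7)
        for Wa, Wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(Wa, Wb)
        assert all(np.abs(W).max() <= 0.5 for W in a.weights)
        assert all(np.abs(bb).max() <= 0.5 for bb in a.biases)

    def test_invalid_topologies_rejected(self):
        with pytest.raises(NeuralNetError):
            Topology((3, 5, 2))  # output must be 1 node
        with pytest.raises(NeuralNetError):
            Topology((3, 0, 1))
        with pytest.raises(NeuralNetError):
            Topology((3, 5, 1), hidden_activation="tanhh")
        with pytest.raises(NeuralNetError):
            init_genotype(Topology.for_window(3), scale=0.0)

    def test_genotype_json_roundtrip(self):
        g = init_genotype(Topology.for_window(5), seed=3)
        h = Genotype.from_json(g.to_json())
        assert h.topology == g.topology
        for Wa, Wb in zip(g.weights, h.weights):
            np.testing.assert_array_equal(Wa, Wb)


class TestForwardPass:
    def test_zero_network_predicts_zero(self):
        t = Topology.for_window(3)
        g = Genotype(
            t,
            [np.zeros((3, 5)), np.zeros((5, 5)), np.zeros((5, 5)), np.zeros((5, 1))],
            [np.zeros((1, 5))] * 3 + [np.zeros((1, 1))],
        )
        np.testing.assert_array_equal(forward_pass(g, [[4.0, 5.0, 6.0]]), [0.0])

    def test_single_neuron_post_activation_bias(self):
        # W=[[2]], b=[[1]], input 3 → relu(6) + 1 = 7 at the hidden layer.
        t = Topology((1, 1, 1), bias_placement="post_activation")
        g = Genotype(
            t,
            [np.array([[2.0]]), np.array([[1.0]])],
            [np.array([[1.0]]), np.array([[0.0]])],
        )
        np.testing.assert_allclose(forward_pass(g, [[3.0]]), [7.0])

    @pytest.mark.parametrize("placement", ["post_activation", "pre_activation"])
    @pytest.mark.parametrize("out_act", ["identity", "relu"])
    def test_matches_per_neuron_oracle(self, placement, out_act, rng):
        t = Topology.for_window(
            3, bias_placement=placement, output_activation=out_act
        )
        g = init_genotype(t, seed=5)
        X = rng.uniform(3, 12, (4, 3))
        np.testing.assert_allclose(
            forward_pass(g, X), forward_oracle(g, X), rtol=1e-12
        )

    def test_relu_hidden_output_before_bias_nonnegative(self, rng):
        # With post-activation bias, a_l - b_l = relu(z_l) must be >= 0.
        from evocgm.neuralnet import _forward_layers

        g = init_genotype(Topology.for_window(4), seed=9)
        X = rng.uniform(3, 12, (8, 4))
        _, acts = _forward_layers(g, X)
        for l, a in enumerate(acts[1:-1]):
            assert (a - g.biases[l]).min() >= -1e-12

    def test_shape_mismatch_rejected(self):
        g = init_genotype(Topology.for_window(3), seed=0)
        with pytest.raises(NeuralNetError):
            forward_pass(g, np.zeros((2, 4)))


def fd_gradients(g, X, y, h=1e-6):
    """Central finite-difference gradients of the dataset MSE."""
    def loss():
        pred = forward_pass(g, X)
        return float(np.mean((y - pred) ** 2))

    gW = [np.zeros_like(W) for W in g.weights]
    gb = [np.zeros_like(b) for b in g.biases]
    for mats, grads in ((g.weights, gW), (g.biases, gb)):
        for M, G in zip(mats, grads):
            it = np.nditer(M, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = M[idx]
                M[idx] = orig + h
                up = loss()
                M[idx] = orig - h
                down = loss()
                M[idx] = orig
                G[idx] = (up - down) / (2 * h)
    return gW, gb


class TestBackprop:
    @pytest.mark.parametrize("placement", ["post_activation", "pre_activation"])
    def test_gradient_matches_finite_differences(self, placement, rng):
        from evocgm.neuralnet import _gradients, _forward_layers

        t = Topology((3, 5, 1), bias_placement=placement)
        g = init_genotype(t, seed=12)
        X = rng.uniform(3, 12, (5, 3))
        y = rng.uniform(3, 12, 5)
        # keep away from ReLU kinks so the numerical derivative is clean
        zs, _ = _forward_layers(g, X)
        assert min(np.abs(z).min() for z in zs) > 1e-4
        aW, ab = _gradients(g, X, y)
        nW, nb = fd_gradients(g, X, y)
        for A, N in zip(aW + ab, nW + nb):
            denom = np.maximum(np.abs(A) + np.abs(N), 1e-8)
            assert (np.abs(A - N) / denom).max() < 1e-5

    def test_zero_lr_returns_input_genotype(self, rng):
        g = init_genotype(Topology.for_window(3), seed=1)
        train = random_dataset(rng, 10, 3)
        val = random_dataset(rng, 5, 3)
        out, _ = backprop_train(g, train, val, lr=0.0, max_epochs=5)
        for Wa, Wb in zip(out.weights, g.weights):
            np.testing.assert_array_equal(Wa, Wb)

    def test_one_step_decreases_train_mse(self, rng):
        g = init_genotype(Topology.for_window(3), seed=2)
        train = random_dataset(rng, 20, 3)
        before = mse_of(g, train)
        out, hist = backprop_train(g, train, train, lr=1e-4, max_epochs=2,
                                   patience=10)
        assert hist.train_mse[1] < before

    def test_single_pair_convergence(self):
        t = Topology.for_window(3)
        g = init_genotype(t, seed=3)
        ds = WindowDataset(np.array([[4.6, 4.3, 4.0]]), np.array([3.8]), 3)
        best, hist = backprop_train(g, ds, ds, lr=0.01, max_epochs=5000,
                                    patience=5000)
        assert mse_of(best, ds) < 1e-4

    def test_divergence_raises_named_epoch(self, rng):
        g = init_genotype(Topology.for_window(3), seed=4)
        train = random_dataset(rng, 50, 3)
        with pytest.raises(DivergenceError) as exc:
            backprop_train(g, train, train, lr=50.0, max_epochs=500, patience=500)
        assert exc.value.epoch > 0

    def test_early_stopping_returns_best_val_epoch(self, rng):
        g = init_genotype(Topology.for_window(3), seed=6)
        train = random_dataset(rng, 30, 3)
        val = random_dataset(rng, 10, 3)
        best, hist = backprop_train(g, train, val, lr=0.005, max_epochs=300)
        assert mse_of(best, val) == pytest.approx(min(hist.val_mse))
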