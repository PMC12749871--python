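"""From-scratch feed-forward network: topology, forward pass, backprop.

The forecasting network is a small fully connected net — window-size
inputs, three hidden layers of five ReLU units, one linear output — whose
parameters are normally *evolved* (see :mod:`evocgm.evolution`) rather
than trained by gradient descent.  A full-batch backpropagation trainer
is included as the comparison baseline.

One unconventional detail is configurable on purpose: where the bias
enters each layer.  The default adds the bias vector *after* the
activation (``a = act(a_prev @ W) + b``); the conventional pre-activation
form (``a = act(a_prev @ W + b)``) is available via
``Topology.bias_placement``.  For the linear output layer the two
coincide.  The gradient code honours whichever placement is configured.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

DEFAULT_HIDDEN = (5, 5, 5)
DEFAULT_INIT_SCALE = 0.5

_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)),
    "identity": (lambda z: z, lambda z: np.ones_like(z)),
}

BIAS_PLACEMENTS = ("post_activation", "pre_activation")


class NeuralNetError(ValueError):
    """Base class for network configuration/shape errors."""


class DivergenceError(RuntimeError):
    """Backprop training produced a non-finite loss."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite training loss at epoch {epoch}")


@dataclass(frozen=True)
class Topology:
    """Layer sizes and activation/bias conventions of a network.

    ``layer_sizes`` runs input → hidden... → output; the first entry must
    equal the window size and the last must be 1 (a single forecast
    value).
    """

    layer_sizes: tuple[int, ...]
    hidden_activation: str = "relu"
    output_activation: str = "identity"
    bias_placement: str = "post_activation"

    def __post_init__(self) -> None:
        object.__setattr__(self, "layer_sizes", tuple(int(s) for s in self.layer_sizes))
        if len(self.layer_sizes) < 2:
            raise NeuralNetError("need at least input and output layers")
        if any(s < 1 for s in self.layer_sizes):
            raise NeuralNetError("all layer sizes must be >= 1")
        if self.layer_sizes[-1] != 1:
            raise NeuralNetError("output layer must have exactly 1 node")
        for act in (self.hidden_activation, self.output_activation):
            if act not in _ACTIVATIONS:
                raise NeuralNetError(f"unknown activation {act!r}")
        if self.bias_placement not in BIAS_PLACEMENTS:
            raise NeuralNetError(f"unknown bias placement {self.bias_placement!r}")

    @classmethod
    def for_window(
        cls,
        window_size: int,
        hidden: tuple[int, ...] = DEFAULT_HIDDEN,
        **kwargs,
    ) -> "Topology":
        return cls((window_size, *hidden, 1), **kwargs)

    @property
    def n_layers(self) -> int:
        return len(self.layer_sizes) - 1

    def activation_of(self, layer: int):
        name = (
            self.output_activation
            if layer == self.n_layers - 1
            else self.hidden_activation
        )
        return _ACTIVATIONS[name]


@dataclass
class Genotype:
    """Weight and bias matrices encoding one network (the GA chromosome).

    ``weights[l]`` has shape ``[n_in(l), n_out(l)]`` and ``biases[l]``
    shape ``[1, n_out(l)]``; shapes chain layer to layer and match the
    topology.
    """

    topology: Topology
    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def __post_init__(self) -> None:
        sizes = self.topology.layer_sizes
        if len(self.weights) != self.topology.n_layers or len(
            self.biases
        ) != self.topology.n_layers:
            raise NeuralNetError("wrong number of weight/bias matrices")
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            if W.shape != (sizes[l], sizes[l + 1]):
                raise NeuralNetError(
                    f"layer {l}: weight shape {W.shape} != "
                    f"({sizes[l]}, {sizes[l + 1]})"
                )
            if b.shape != (1, sizes[l + 1]):
                raise NeuralNetError(
                    f"layer {l}: bias shape {b.shape} != (1, {sizes[l + 1]})"
                )

    @property
    def n_params(self) -> int:
        return sum(W.size for W in self.weights) + sum(b.size for b in self.biases)

    def copy(self) -> "Genotype":
        return Genotype(
            self.topology,
            [W.copy() for W in self.weights],
            [b.copy() for b in self.biases],
        )

    def to_json(self) -> str:
        doc = {
            "topology": {
                "layer_sizes": list(self.topology.layer_sizes),
                "hidden_activation": self.topology.hidden_activation,
                "output_activation": self.topology.output_activation,
                "bias_placement": self.topology.bias_placement,
            },
            "weights": [W.tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "Genotype":
        doc = json.loads(text)
        topo = Topology(
            tuple(doc["topology"]["layer_sizes"]),
            hidden_activation=doc["topology"]["hidden_activation"],
            output_activation=doc["topology"]["output_activation"],
            bias_placement=doc["topology"]["bias_placement"],
        )
        return cls(
            topo,
            [np.asarray(W, dtype=float) for W in doc["weights"]],
            [np.asarray(b, dtype=float) for b in doc["biases"]],
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "Genotype":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(fh.read())


@dataclass
class TrainHistory:
    """Per-iteration training/validation error and the stop reason."""

    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    stop_reason: str = ""

    @property
    def iterations(self) -> int:
        return len(self.train_mse)


def init_genotype(
    topology: Topology,
    scale: float = DEFAULT_INIT_SCALE,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Genotype:
    """Draw every weight and bias independently uniform in [-scale, scale]."""
    if scale <= 0:
        raise NeuralNetError("init scale must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    sizes = topology.layer_sizes
    weights = [
        rng.uniform(-scale, scale, size=(sizes[l], sizes[l + 1]))
        for l in range(topology.n_layers)
    ]
    biases = [
        rng.uniform(-scale, scale, size=(1, sizes[l + 1]))
        for l in range(topology.n_layers)
    ]
    return Genotype(topology, weights, biases)


def _forward_layers(g: Genotype, X: np.ndarray):
    """Forward pass keeping per-layer pre-activations (for backprop)."""
    a = X
    zs, acts = [], [a]
    for l in range(g.topology.n_layers):
        act, _ = g.topology.activation_of(l)
        if g.topology.bias_placement == "post_activation":
            z = a @ g.weights[l]
            a = act(z) + g.biases[l]
        else:
            z = a @ g.weights[l] + g.biases[l]
            a = act(z)
        zs.append(z)
        acts.append(a)
    return zs, acts


def forward_pass(g: Genotype, inputs: np.ndarray) -> np.ndarray:
    """Network predictions for a batch of input rows, shape ``[N]``."""
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    if X.shape[1] != g.topology.layer_sizes[0]:
        raise NeuralNetError(
            f"input width {X.shape[1]} != topology input size "
            f"{g.topology.layer_sizes[0]}"
        )
    _, acts = _forward_layers(g, X)
    return acts[-1][:, 0]


def _gradients(g: Genotype, X: np.ndarray, y: np.ndarray):
    """Analytic MSE gradients w.r.t. every weight and bias matrix."""
    n = len(y)
    zs, acts = _forward_layers(g, X)
    # dL/da for the output layer; L = mean((a - y)^2).
    delta_a = 2.0 * (acts[-1] - y[:, None]) / n
    gW = [None] * g.topology.n_layers
    gb = [None] * g.topology.n_layers
    for l in range(g.topology.n_layers - 1, -1, -1):
        _, dact = g.topology.activation_of(l)
        if g.topology.bias_placement == "post_activation":
            # a = act(z) + b : bias gradient bypasses the activation.
            gb[l] = delta_a.sum(axis=0, keepdims=True)
            delta_z = delta_a * dact(zs[l])
        else:
            # a = act(z + b); zs[l] already includes b.
            delta_z = delta_a * dact(zs[l])
            gb[l] = delta_z.sum(axis=0, keepdims=True)
        gW[l] = acts[l].T @ delta_z
        delta_a = delta_z @ g.weights[l].T
    return gW, gb


def mse_of(g: Genotype, ds) -> float:
    """Mean squared error of a genotype on a window dataset."""
    pred = forward_pass(g, ds.inputs)
    return float(np.mean((ds.targets - pred) ** 2))


def backprop_train(
    g: Genotype,
    train,
    val,
    lr: float = 0.01,
    max_epochs: int = 500,
    patience: int = 3,
) -> tuple[Genotype, TrainHistory]:
    """Full-batch gradient descent with validation-based early stopping.

    Stops when the validation MSE has strictly increased for ``patience``
    consecutive epochs (the same rule the evolutionary loop uses) or
    after ``max_epochs``; the returned genotype carries the parameters of
    the best-validation epoch.  A non-finite loss raises
    :class:`DivergenceError` naming the epoch.
    """
    if lr < 0:
        raise NeuralNetError("learning rate must be >= 0")
    if len(train) == 0 or len(val) == 0:
        raise NeuralNetError("training and validation sets must be non-empty")
    current = g.copy()
    history = TrainHistory()
    best = current.copy()
    best_val = np.inf
    increases = 0
    prev_val = np.inf

    for epoch in range(max_epochs):
        t_mse = mse_of(current, train)
        v_mse = mse_of(current, val)
        if not (np.isfinite(t_mse) and np.isfinite(v_mse)):
            raise DivergenceError(epoch)
        history.train_mse.append(t_mse)
        history.val_mse.append(v_mse)
        if v_mse < best_val:
            best_val = v_mse
            best = current.copy()
        if v_mse > prev_val:
            increases += 1
            if increases >= patience:
                history.stop_reason = "early_stop"
                return best, history
        else:
            increases = 0
        prev_val = v_mse

        gW, gb = _gradients(current, train.inputs, train.targets)
        for l in range(current.topology.n_layers):
            current.weights[l] -= lr * gW[l]
            current.biases[l] -= lr * gb[l]

    history.stop_reason = "max_epochs"
    return best, history
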