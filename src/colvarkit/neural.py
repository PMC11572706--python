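"""Dense feed-forward neural-network collective variables.

A network maps a vector of upstream CV values through layers
x_k = f_k(W_k x_{k-1} + b_k); the last layer's outputs are CV values.
Activations: linear, tanh, sigmoid, relu (relu subgradient at 0 is 0).
Jacobians are exact, chain-ruled through stored pre-activations.

Weights live in a plain-text, diff-able file::

    layers N_0 N_1 ... N_L
    activations a_1 ... a_L
    # then for each layer k = 1..L:
    #   N_k rows of N_{k-1} weights, then one row of N_k biases
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NetworkSpec", "network_forward", "load_network", "save_network",
           "NeuralNetworkCV", "stack_networks"]

_ACTIVATIONS = ("linear", "tanh", "sigmoid", "relu")


def _act(name: str, x: np.ndarray):
    if name == "linear":
        return x, np.ones_like(x)
    if name == "tanh":
        t = np.tanh(x)
        return t, 1.0 - t * t
    if name == "sigmoid":
        s = 1.0 / (1.0 + np.exp(-x))
        return s, s * (1.0 - s)
    if name == "relu":
        # subgradient at exactly 0 fixed to 0
        return np.maximum(x, 0.0), (x > 0.0).astype(float)
    raise ValueError(f"unknown activation {name!r}")


@dataclass
class NetworkSpec:
    """Validated layer sizes, weights, biases and activation names."""

    layer_sizes: list  # N_0 ... N_L
    weights: list  # L matrices, W_k of shape (N_k, N_{k-1})
    biases: list  # L vectors of length N_k
    activations: list  # L names

    def __post_init__(self) -> None:
        L = len(self.layer_sizes) - 1
        if not (len(self.weights) == len(self.biases)
                == len(self.activations) == L):
            raise ValueError("layer count mismatch")
        for k in range(L):
            nk, nprev = self.layer_sizes[k + 1], self.layer_sizes[k]
            W = np.asarray(self.weights[k], dtype=float)
            b = np.asarray(self.biases[k], dtype=float)
            if W.shape != (nk, nprev):
                raise ValueError(
                    f"layer {k + 1}: weight shape {W.shape} does not match "
                    f"declared sizes ({nk}, {nprev})")
            if b.shape != (nk,):
                raise ValueError(f"layer {k + 1}: bias length {b.shape[0]} != {nk}")
            if not (np.all(np.isfinite(W)) and np.all(np.isfinite(b))):
                raise ValueError(f"layer {k + 1}: non-finite weights")
            if self.activations[k] not in _ACTIVATIONS:
                raise ValueError(f"unknown activation name {self.activations[k]!r}")
            self.weights[k] = W
            self.biases[k] = b


def network_forward(spec: NetworkSpec, inputs):
    """Outputs and the exact Jacobian d outputs / d inputs."""
    x = np.asarray(inputs, dtype=float)
    if x.shape != (spec.layer_sizes[0],):
        raise ValueError(f"input length {x.shape} != N_0 = {spec.layer_sizes[0]}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite network input")
    J = np.eye(spec.layer_sizes[0])
    for W, b, act in zip(spec.weights, spec.biases, spec.activations):
        pre = W @ x + b
        x, dact = _act(act, pre)
        J = (dact[:, None] * W) @ J
    return x, J


def stack_networks(a: NetworkSpec, b: NetworkSpec) -> NetworkSpec:
    """Concatenate two networks (outputs of ``a`` feed ``b``)."""
    if a.layer_sizes[-1] != b.layer_sizes[0]:
        raise ValueError("output/input sizes do not match")
    return NetworkSpec(list(a.layer_sizes) + list(b.layer_sizes[1:]),
                       list(a.weights) + list(b.weights),
                       list(a.biases) + list(b.biases),
                       list(a.activations) + list(b.activations))


def save_network(spec: NetworkSpec, path) -> None:
    with open(path, "w") as fh:
        fh.write("layers " + " ".join(str(n) for n in spec.layer_sizes) + "\n")
        fh.write("activations " + " ".join(spec.activations) + "\n")
        for W, b in zip(spec.weights, spec.biases):
            for row in W:
                fh.write(" ".join("%.17g" % v for v in row) + "\n")
            fh.write(" ".join("%.17g" % v for v in b) + "\n")


def load_network(path) -> NetworkSpec:
    with open(path) as fh:
        tokens = fh.readline().split()
        if tokens[:1] != ["layers"]:
            raise ValueError("weight file must start with a 'layers' line")
        sizes = [int(t) for t in tokens[1:]]
        atoks = fh.readline().split()
        if atoks[:1] != ["activations"]:
            raise ValueError("second line must be 'activations'")
        acts = atoks[1:]
        if len(acts) != len(sizes) - 1:
            raise ValueError("one activation per layer required")
        numbers = [float(t) for line in fh for t in line.split()]
    weights, biases = [], []
    pos = 0
    for k in range(len(sizes) - 1):
        nk, nprev = sizes[k + 1], sizes[k]
        need = nk * nprev + nk
        block = numbers[pos:pos + need]
        if len(block) != need:
            raise ValueError(f"layer {k + 1}: expected {need} numbers, "
                             f"file ran out after {len(block)}")
        weights.append(np.array(block[:nk * nprev]).reshape(nk, nprev))
        biases.append(np.array(block[nk * nprev:]))
        pos += need
    if pos != len(numbers):
        raise ValueError("trailing numbers after last layer")
    return NetworkSpec(sizes, weights, biases, acts)


class NeuralNetworkCV:
    """A scalar CV: one output component of a network over child CVs."""

    periodic = False
    period = 360.0

    def __init__(self, spec: NetworkSpec, components, output_index: int = 0):
        if len(components) != spec.layer_sizes[0]:
            raise ValueError("one child component per network input required")
        self.spec = spec
        self.components = list(components)
        self.output_index = int(output_index)

    def evaluate(self, positions):
        vals, grads = [], []
        for comp in self.components:
            v, g = comp.evaluate(positions)
            vals.append(v)
            grads.append(g)
        out, J = network_forward(self.spec, np.array(vals))
        row = J[self.output_index]
        g = np.zeros_like(np.asarray(positions, dtype=float))
        for d, gv in zip(row, grads):
            g += d * gv
        return float(out[self.output_index]), g
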