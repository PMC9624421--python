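"""From-scratch sigmoid networks and their learning rules.

Implements the 16 candidate architectures screened by the pipeline:
feedforward networks with 0, 1, 2, 3, 5, 7 or 10 hidden layers of 100
logistic units, and a recurrent network whose hidden population is a
fully connected circuit iterated to a fixed point before the output
layer is read — each variant optionally preceded by a 50-unit
autoencoder layer whose encoder weights are pretrained on the inputs
and then frozen.

Learning is plain stochastic gradient descent on a masked
sum-of-squares loss: unreported outcome cells contribute neither error
nor gradient. The depth-0 network's update is the classic delta rule,
obtained here as backpropagation specialised to no hidden layers (one
code path). The recurrent gradient uses fixed-point adjoint iteration
(recurrent backpropagation in the Pineda/Almeida sense): the settled
state is treated as an implicit function of the weights and the adjoint
system is iterated to the same tolerance as the forward settling.

All arrays follow the row convention: activations are (batch, units)
and a layer computes ``sigmoid(a @ W + b)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

HIDDEN_DEPTHS = (0, 1, 2, 3, 5, 7, 10)


def sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SettlingError(RuntimeError):
    """Recurrent settling (or its adjoint) failed to converge."""


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture descriptor for one of the candidate network types."""

    kind: str = "feedforward"          # "feedforward" | "recurrent"
    hidden_layers: int = 0             # ignored for recurrent (one circuit)
    hidden_units: int = 100
    autoencoder_units: int | None = None
    input_dim: int = 17
    output_dim: int = 26

    def __post_init__(self) -> None:
        if self.kind not in ("feedforward", "recurrent"):
            raise ValueError(f"unknown network kind {self.kind!r}")
        if self.kind == "feedforward" and self.hidden_layers not in range(0, 64):
            raise ValueError("hidden_layers must be a small nonnegative integer")

    @property
    def label(self) -> str:
        core = (f"ff{self.hidden_layers}" if self.kind == "feedforward"
                else "recurrent")
        return core + (f"+ae{self.autoencoder_units}" if self.autoencoder_units
                       else "")

    def layer_dims(self) -> list[int]:
        """Unit counts of the feedforward chain after the optional encoder."""
        first = self.autoencoder_units or self.input_dim
        if self.kind == "recurrent":
            return [first, self.hidden_units, self.output_dim]
        return [first] + [self.hidden_units] * self.hidden_layers + [self.output_dim]

    def n_parameters(self) -> int:
        dims = self.layer_dims()
        n = sum(a * b + b for a, b in zip(dims, dims[1:]))
        if self.kind == "recurrent":
            n += self.hidden_units ** 2
        if self.autoencoder_units:
            n += self.input_dim * self.autoencoder_units + self.autoencoder_units
        return n


def candidate_network_specs(hidden_units: int = 100,
                            autoencoder_units: int = 50,
                            input_dim: int = 17,
                            output_dim: int = 26) -> list[NetworkSpec]:
    """The 16 screened types: {ff x 7 depths, recurrent} x {plain, +autoencoder}."""
    specs = []
    for ae in (None, autoencoder_units):
        for depth in HIDDEN_DEPTHS:
            specs.append(NetworkSpec("feedforward", depth, hidden_units, ae,
                                     input_dim, output_dim))
        specs.append(NetworkSpec("recurrent", 1, hidden_units, ae,
                                 input_dim, output_dim))
    return specs


@dataclass
class WeightSet:
    """Trainable parameters implied by a :class:`NetworkSpec`.

    ``weights[i]``/``biases[i]`` are the feedforward chain (for the
    recurrent kind: [W_in, W_out] and [b_hidden, b_output], with the
    circuit's recurrent matrix in ``w_rec``). ``encoder`` holds the
    frozen input->autoencoder map and is excluded from every update.
    """

    spec: NetworkSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    w_rec: np.ndarray | None = None
    encoder: tuple[np.ndarray, np.ndarray] | None = None

    def copy(self) -> "WeightSet":
        return WeightSet(
            self.spec,
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            None if self.w_rec is None else self.w_rec.copy(),
            None if self.encoder is None else
            (self.encoder[0].copy(), self.encoder[1].copy()),
        )

    # -- flat views over the *trainable* parameters (for gradient checks) --
    def _arrays(self) -> list[np.ndarray]:
        arrs = list(self.weights) + list(self.biases)
        if self.w_rec is not None:
            arrs.append(self.w_rec)
        return arrs

    def pack(self) -> np.ndarray:
        return np.concatenate([a.ravel() for a in self._arrays()])

    def unpack(self, theta: np.ndarray) -> None:
        pos = 0
        for a in self._arrays():
            a[...] = theta[pos:pos + a.size].reshape(a.shape)
            pos += a.size

    def to_dict(self) -> dict:
        d = {
            "spec": self.spec.__dict__ | {},
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }
        if self.w_rec is not None:
            d["w_rec"] = self.w_rec.tolist()
        if self.encoder is not None:
            d["encoder"] = [self.encoder[0].tolist(), self.encoder[1].tolist()]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "WeightSet":
        return cls(
            NetworkSpec(**d["spec"]),
            [np.asarray(w, dtype=float) for w in d["weights"]],
            [np.asarray(b, dtype=float) for b in d["biases"]],
            np.asarray(d["w_rec"], dtype=float) if "w_rec" in d else None,
            tuple(np.asarray(a, dtype=float) for a in d["encoder"])
            if "encoder" in d else None,
        )


@dataclass
class Activations:
    """Per-layer activations for one forward pass (batch-first)."""

    layers: list[np.ndarray]
    settled_state: np.ndarray | None = None
    settling_steps: int = 0

    @property
    def output(self) -> np.ndarray:
        return self.layers[-1]


def init_network(spec: NetworkSpec, seed: int) -> WeightSet:
    """Uniform(-1/sqrt(fan_in), +1/sqrt(fan_in)) weights, zero biases.

    Deterministic for a given seed. When the spec carries an
    autoencoder, the encoder slot is initialised too (it is normally
    replaced by :func:`pretrain_autoencoder` before training).
    """
    rng = np.random.default_rng(seed)

    def draw(n_in: int, n_out: int, fan_in: int | None = None) -> np.ndarray:
        r = 1.0 / np.sqrt(fan_in if fan_in is not None else n_in)
        return rng.uniform(-r, r, size=(n_in, n_out))

    dims = spec.layer_dims()
    ws = WeightSet(spec, [], [])
    if spec.autoencoder_units:
        ws.encoder = (draw(spec.input_dim, spec.autoencoder_units),
                      np.zeros(spec.autoencoder_units))
    if spec.kind == "recurrent":
        d, h, o = dims
        fan = d + h  # circuit units see the input and each other
        ws.weights = [draw(d, h, fan), draw(h, o)]
        ws.biases = [np.zeros(h), np.zeros(o)]
        ws.w_rec = draw(h, h, fan)
    else:
        for a, b in zip(dims, dims[1:]):
            ws.weights.append(draw(a, b))
            ws.biases.append(np.zeros(b))
    return ws


SETTLE_TOL = 1e-8
SETTLE_MAX_STEPS = 500


def _settle(ws: WeightSet, x: np.ndarray) -> tuple[np.ndarray, int]:
    """Iterate s <- sigmoid(x W_in + s W_rec + b) from 0.5 to a fixed point."""
    w_in, b = ws.weights[0], ws.biases[0]
    drive = x @ w_in + b
    s = np.full((x.shape[0], w_in.shape[1]), 0.5)
    for step in range(1, SETTLE_MAX_STEPS + 1):
        s_new = sigmoid(drive + s @ ws.w_rec)
        if np.max(np.abs(s_new - s)) < SETTLE_TOL:
            return s_new, step
        s = s_new
    raise SettlingError(
        f"hidden circuit did not settle within {SETTLE_MAX_STEPS} steps")


def forward(ws: WeightSet, X: np.ndarray) -> Activations:
    """Forward pass for a (batch, input_dim) matrix of scaled inputs."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != ws.spec.input_dim:
        raise ValueError(f"expected inputs of width {ws.spec.input_dim}")
    layers = [X]
    a = X
    if ws.encoder is not None:
        a = sigmoid(a @ ws.encoder[0] + ws.encoder[1])
        layers.append(a)
    if ws.spec.kind == "recurrent":
        s, steps = _settle(ws, a)
        layers.append(s)
        out = sigmoid(s @ ws.weights[1] + ws.biases[1])
        layers.append(out)
        return Activations(layers, settled_state=s, settling_steps=steps)
    for w, b in zip(ws.weights, ws.biases):
        a = sigmoid(a @ w + b)
        layers.append(a)
    return Activations(layers)


def _adjoint_settle(ws: WeightSet, g: np.ndarray, sp: np.ndarray) -> np.ndarray:
    """Solve u = sp * (g + u @ W_rec.T) by iteration (fixed-point adjoint).

    ``g`` is dE/ds at the settled state, ``sp`` the sigmoid derivative
    there; the solution u is dE/dz for the circuit's net input z.
    """
    u = sp * g
    for _ in range(SETTLE_MAX_STEPS):
        u_new = sp * (g + u @ ws.w_rec.T)
        if np.max(np.abs(u_new - u)) < SETTLE_TOL:
            return u_new
        u = u_new
    raise SettlingError("adjoint iteration did not settle")


def loss_and_gradient(
    ws: WeightSet, X: np.ndarray, Y: np.ndarray, mask: np.ndarray,
) -> tuple[float, WeightSet]:
    """Mean masked half-SSE over the batch and its gradient.

    loss = mean over patterns of 1/2 * sum_{k observed} (t_k - o_k)^2.
    Masked-out outputs contribute zero error and zero gradient; the
    frozen encoder receives no gradient (its slot in the returned
    structure is None).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    mask = np.atleast_2d(np.asarray(mask, dtype=bool))
    n = X.shape[0]
    acts = forward(ws, X)
    out = acts.output
    err = np.where(mask, out - np.where(mask, Y, 0.0), 0.0)
    loss = 0.5 * float(np.sum(err ** 2)) / n

    grad = WeightSet(ws.spec,
                     [np.zeros_like(w) for w in ws.weights],
                     [np.zeros_like(b) for b in ws.biases],
                     None if ws.w_rec is None else np.zeros_like(ws.w_rec))

    delta_out = (err * out * (1.0 - out)) / n  # dE/dz at the output layer
    if ws.spec.kind == "recurrent":
        s = acts.settled_state
        grad.weights[1] = s.T @ delta_out
        grad.biases[1] = delta_out.sum(axis=0)
        g_s = delta_out @ ws.weights[1].T        # dE/ds at the fixed point
        u = _adjoint_settle(ws, g_s, s * (1.0 - s))
        a_in = acts.layers[1] if ws.encoder is not None else acts.layers[0]
        grad.weights[0] = a_in.T @ u
        grad.biases[0] = u.sum(axis=0)
        grad.w_rec = s.T @ u
        return loss, grad

    # feedforward chain: acts.layers = [x, (enc), h1, ..., out]
    first = 2 if ws.encoder is not None else 1
    delta = delta_out
    for i in range(len(ws.weights) - 1, -1, -1):
        a_prev = acts.layers[first + i - 1]
        grad.weights[i] = a_prev.T @ delta
        grad.biases[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ ws.weights[i].T) * a_prev * (1.0 - a_prev)
    return loss, grad


def sgd_step(ws: WeightSet, X: np.ndarray, Y: np.ndarray, mask: np.ndarray,
             learning_rate: float) -> WeightSet:
    """One gradient-descent update on the mean batch gradient (in place).

    Frozen encoder weights are untouched; returns ``ws`` for chaining.
    """
    _, grad = loss_and_gradient(ws, X, Y, mask)
    apply_gradient(ws, grad, learning_rate)
    return ws


def apply_gradient(ws: WeightSet, grad: WeightSet, learning_rate: float) -> None:
    for w, g in zip(ws.weights, grad.weights):
        w -= learning_rate * g
    for b, g in zip(ws.biases, grad.biases):
        b -= learning_rate * g
    if ws.w_rec is not None:
        ws.w_rec -= learning_rate * grad.w_rec


def pretrain_autoencoder(
    inputs: np.ndarray, units: int, *,
    learning_rate: float = 0.5, batch_size: int = 8,
    iterations: int = 5000, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Train an input->units->input reconstruction net; return the encoder.

    The returned (weights, biases) pair maps the scaled 17-dim input to
    the autoencoder representation and is meant to be installed frozen
    (``WeightSet.encoder``) in a downstream network.
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    n, d = inputs.shape
    spec = NetworkSpec("feedforward", 1, units, None, input_dim=d, output_dim=d)
    ws = init_network(spec, seed)
    rng = np.random.default_rng(seed + 1)
    mask = np.ones((batch_size, d), dtype=bool)
    consumed = 0
    while consumed < iterations:
        b = min(batch_size, iterations - consumed)
        idx = rng.integers(0, n, size=b)
        sgd_step(ws, inputs[idx], inputs[idx], mask[:b], learning_rate)
        consumed += b
    return ws.weights[0].copy(), ws.biases[0].copy()


def reconstruction_rms(encoder_ws: WeightSet, inputs: np.ndarray) -> float:
    out = forward(encoder_ws, inputs).output
    return float(np.sqrt(np.mean((out - inputs) ** 2)))
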