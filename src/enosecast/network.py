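"""Single-hidden-layer feedforward (BP) network, written from scratch.

Hidden activation is the logistic sigmoid; the output layer is linear
(identity), so classifier outputs may be negative.  The loss is mean squared
error for both regression and one-hot classification.  A flat parameter
codec (W1 row-major, b1, W2 row-major, b2) lets a metaheuristic optimize the
weights and thresholds as a single bounded vector.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DivergenceError, ParameterError

__all__ = [
    "NetworkTopology",
    "NetworkParams",
    "forward",
    "mse_loss",
    "gradients",
    "train_gd",
    "params_to_vector",
    "vector_to_params",
    "random_params",
]


@dataclass(frozen=True)
class NetworkTopology:
    n_in: int
    n_hidden: int
    n_out: int

    def __post_init__(self):
        if min(self.n_in, self.n_hidden, self.n_out) < 1:
            raise ParameterError("all layer sizes must be >= 1")

    @property
    def n_params(self) -> int:
        return (
            self.n_in * self.n_hidden
            + self.n_hidden
            + self.n_hidden * self.n_out
            + self.n_out
        )


@dataclass
class NetworkParams:
    """Weights and thresholds (biases) of one network."""

    w1: np.ndarray  # (n_in, n_hidden)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden, n_out)
    b2: np.ndarray  # (n_out,)

    def __post_init__(self):
        for name in ("w1", "b1", "w2", "b2"):
            a = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(a)):
                raise ParameterError(f"non-finite values in {name}")
            setattr(self, name, a)
        if self.w1.shape[1] != self.b1.shape[0] or self.w2.shape[0] != self.b1.shape[0]:
            raise ParameterError("hidden-layer shapes are inconsistent")
        if self.w2.shape[1] != self.b2.shape[0]:
            raise ParameterError("output-layer shapes are inconsistent")

    @property
    def topology(self) -> NetworkTopology:
        return NetworkTopology(self.w1.shape[0], self.w1.shape[1], self.w2.shape[1])

    def copy(self) -> "NetworkParams":
        return NetworkParams(self.w1.copy(), self.b1.copy(), self.w2.copy(), self.b2.copy())


def _sigmoid(z):
    # numerically stable logistic
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def forward(params: NetworkParams, x: np.ndarray) -> np.ndarray:
    """Network output: W2^T sigmoid(W1^T x + b1) + b2.

    Accepts a single input vector (returns a vector) or a batch of rows
    (returns a matrix).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xb = x[None, :] if single else x
    if xb.shape[1] != params.w1.shape[0]:
        raise ParameterError(
            f"input length {xb.shape[1]} != n_in {params.w1.shape[0]}"
        )
    h = _sigmoid(xb @ params.w1 + params.b1)
    y = h @ params.w2 + params.b2
    return y[0] if single else y


def mse_loss(params: NetworkParams, x: np.ndarray, y: np.ndarray) -> float:
    """Mean squared error over all samples and output units."""
    pred = forward(params, np.atleast_2d(x))
    with np.errstate(over="ignore"):  # overflow -> inf, reported as divergence
        return float(np.mean((pred - np.atleast_2d(y)) ** 2))


def gradients(params: NetworkParams, x: np.ndarray, y: np.ndarray) -> NetworkParams:
    """Analytic gradient of :func:`mse_loss` with respect to every parameter."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n, n_out = y.shape[0], params.b2.shape[0]
    h = _sigmoid(x @ params.w1 + params.b1)
    pred = h @ params.w2 + params.b2
    # d loss / d pred for loss = mean over (n * n_out) squared errors
    delta_out = 2.0 * (pred - y) / (n * n_out)
    gw2 = h.T @ delta_out
    gb2 = delta_out.sum(axis=0)
    delta_h = (delta_out @ params.w2.T) * h * (1.0 - h)
    gw1 = x.T @ delta_h
    gb1 = delta_h.sum(axis=0)
    return NetworkParams(gw1, gb1, gw2, gb2)


def random_params(
    topology: NetworkTopology, seed: int = 0, scale: float = 0.5
) -> NetworkParams:
    """Seeded uniform initialization in [-scale, scale]."""
    rng = np.random.default_rng(seed)
    return NetworkParams(
        w1=rng.uniform(-scale, scale, (topology.n_in, topology.n_hidden)),
        b1=rng.uniform(-scale, scale, topology.n_hidden),
        w2=rng.uniform(-scale, scale, (topology.n_hidden, topology.n_out)),
        b2=rng.uniform(-scale, scale, topology.n_out),
    )


def train_gd(
    x: np.ndarray,
    y: np.ndarray,
    topology: NetworkTopology | None = None,
    learning_rate: float = 0.05,
    epochs: int = 1000,
    seed: int = 0,
    init: NetworkParams | None = None,
) -> tuple[NetworkParams, np.ndarray]:
    """Full-batch gradient descent on MSE.

    Either ``topology`` (for a fresh seeded init uniform in [-0.5, 0.5]) or
    ``init`` (warm start, e.g. from a metaheuristic) must be given.  Returns
    the trained parameters and the per-epoch loss curve.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if init is None:
        if topology is None:
            raise ParameterError("either topology or init must be provided")
        params = random_params(topology, seed)
    else:
        params = init.copy()
    losses = np.empty(epochs)
    for e in range(epochs):
        g = gradients(params, x, y)
        params.w1 -= learning_rate * g.w1
        params.b1 -= learning_rate * g.b1
        params.w2 -= learning_rate * g.w2
        params.b2 -= learning_rate * g.b2
        losses[e] = mse_loss(params, x, y)
        if not np.isfinite(losses[e]):
            raise DivergenceError(
                f"training diverged at epoch {e} (loss is non-finite); "
                "try a smaller learning rate"
            )
    return params, losses


def params_to_vector(params: NetworkParams) -> np.ndarray:
    """Flatten parameters in the fixed order W1 (row-major), b1, W2, b2."""
    return np.concatenate(
        [params.w1.ravel(), params.b1, params.w2.ravel(), params.b2]
    )


def vector_to_params(vector: np.ndarray, topology: NetworkTopology) -> NetworkParams:
    """Inverse of :func:`params_to_vector`; exact roundtrip."""
    v = np.asarray(vector, dtype=float).ravel()
    if v.shape[0] != topology.n_params:
        raise ParameterError(
            f"vector length {v.shape[0]} != expected {topology.n_params} "
            f"for topology {topology}"
        )
    i = 0
    w1 = v[i : i + topology.n_in * topology.n_hidden].reshape(
        topology.n_in, topology.n_hidden
    )
    i += w1.size
    b1 = v[i : i + topology.n_hidden]
    i += topology.n_hidden
    w2 = v[i : i + topology.n_hidden * topology.n_out].reshape(
        topology.n_hidden, topology.n_out
    )
    i += w2.size
    b2 = v[i : i + topology.n_out]
    return NetworkParams(w1.copy(), b1.copy(), w2.copy(), b2.copy())
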