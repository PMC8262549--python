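"""Minimal feed-forward neural-network primitives (NumPy, explicit backprop).

Just enough machinery for the two networks this package trains: a per-site
overcomplete autoencoder with mixed reconstruction heads, and a tabular
classifier with categorical embeddings.  Gradients are averaged over the
mini-batch; all randomness flows through a caller-supplied Generator, so
training is bit-deterministic given a seed.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable array with an accumulated gradient.

    ``decay=True`` marks dense weight matrices, the only parameters subject
    to weight decay (biases and embedding tables are exempt).
    """

    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = False):
        self.value = value
        self.grad = np.zeros_like(value)
        self.decay = decay

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Dense:
    """Affine layer y = xW + b, uniform fan-in initialization U(±1/sqrt(n_in))."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        limit = 1.0 / np.sqrt(n_in)
        self.W = Parameter(rng.uniform(-limit, limit, size=(n_in, n_out)), decay=True)
        self.b = Parameter(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value.T

    @property
    def params(self) -> list[Parameter]:
        return [self.W, self.b]


class ReLU:
    params: list[Parameter] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, 0.0)


class MLP:
    """Dense/ReLU stack.  ``relu_last`` keeps a nonlinearity after the final
    Dense (used for the encoder, whose post-activation output is the code)."""

    def __init__(self, rng: np.random.Generator, dims: list[int], relu_last: bool = True):
        self.layers: list = []
        for i in range(len(dims) - 1):
            self.layers.append(Dense(rng, dims[i], dims[i + 1]))
            if relu_last or i < len(dims) - 2:
                self.layers.append(ReLU())

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    @property
    def params(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.params]


class EmbeddingSet:
    """One learned lookup table per categorical column; outputs concatenated.

    ``cardinalities`` are effective cardinalities (including any reserved
    missing level); ``widths`` the per-column embedding widths.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        cardinalities: list[int],
        widths: list[int],
    ):
        self.tables = [
            Parameter(rng.uniform(-0.05, 0.05, size=(c, w)))
            for c, w in zip(cardinalities, widths)
        ]
        self.widths = list(widths)

    @property
    def out_width(self) -> int:
        return sum(self.widths)

    def forward(self, codes: np.ndarray) -> np.ndarray:
        self._codes = codes
        if not self.tables:
            return np.empty((codes.shape[0], 0))
        return np.concatenate(
            [t.value[codes[:, j]] for j, t in enumerate(self.tables)], axis=1
        )

    def backward(self, g: np.ndarray) -> None:
        off = 0
        for j, t in enumerate(self.tables):
            w = self.widths[j]
            np.add.at(t.grad, self._codes[:, j], g[:, off : off + w])
            off += w

    @property
    def params(self) -> list[Parameter]:
        return list(self.tables)


# ---------------------------------------------------------------------------
# Optimizers


class SGD:
    """Plain SGD with coupled L2 weight decay on decay-marked parameters.

    The learning rate is mutable so a per-epoch decay schedule can be applied
    between epochs by the training loop.
    """

    def __init__(self, params: list[Parameter], lr: float, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay

    def step(self) -> None:
        for p in self.params:
            g = p.grad
            if p.decay and self.weight_decay:
                g = g + self.weight_decay * p.value
            p.value -= self.lr * g
            p.zero_grad()


class Adam:
    """Adam with bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            p.zero_grad()


# ---------------------------------------------------------------------------
# Losses (value + gradient w.r.t. logits; both averaged over the batch)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of integer ``targets`` under softmax ``logits``."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(np.clip(p[np.arange(n), targets], 1e-12, None)).mean()
    grad = p
    grad[np.arange(n), targets] -= 1.0
    return float(loss), grad / n


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits (numerically stable softplus form)."""
    n = z.shape[0]
    loss = (np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))).mean()
    grad = (sigmoid(z) - y) / n
    return float(loss), grad
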