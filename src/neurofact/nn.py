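"""Small neural-network building blocks on top of :mod:`neurofact.autodiff`.

Linear layers, an MLP container, global-norm gradient clipping, and Adam.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .autodiff import Tensor

_ACTIVATIONS = {"tanh", "relu", "softplus", "identity"}


def _activate(x: Tensor, name: str) -> Tensor:
    if name == "tanh":
        return x.tanh()
    if name == "relu":
        return x.relu()
    if name == "softplus":
        return x.softplus()
    if name == "identity":
        return x
    raise ValueError(f"unknown activation {name!r}")


class Linear:
    """Affine map with Glorot-scaled Gaussian init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.W = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out

    def parameters(self) -> list[Tensor]:
        return [self.W] + ([self.b] if self.b is not None else [])


class MLP:
    """Stack of Linear layers with a fixed activation between them.

    The final layer is linear (no activation). With `hidden=()` this reduces
    to a single affine (or purely linear, if `bias=False`) map.
    """

    def __init__(self, n_in: int, hidden: Iterable[int], n_out: int,
                 rng: np.random.Generator, activation: str = "tanh",
                 bias: bool = True):
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        dims = [n_in, *hidden, n_out]
        self.layers = [Linear(dims[i], dims[i + 1], rng, bias=bias)
                       for i in range(len(dims) - 1)]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = _activate(x, self.activation)
        return x

    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters()]


def clip_grad_norm(params: list[Tensor], max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most `max_norm`."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    norm = np.sqrt(total)
    if norm > max_norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


class Adam:
    """Adaptive-moment gradient descent (bias-corrected)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
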