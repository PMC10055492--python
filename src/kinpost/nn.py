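"""Minimal fully-connected network engine with explicit backpropagation.

The posterior estimators in :mod:`kinpost.cvae` are small multilayer
perceptrons (at most four hidden layers of width <= 128), trained by plain
stochastic gradient descent with momentum.  This module provides exactly the
pieces they need — linear layers, rectified-linear activations, He-style
initialization, and an SGD-with-momentum update — operating on numpy arrays
with analytically coded gradients.  Gradient correctness is pinned down by
finite-difference checks in the test suite.

Shapes follow the (batch, features) convention throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Linear", "MLP", "SGDMomentum"]


class Linear:
    """Affine layer ``x -> x @ W + b`` with cached input for backprop."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        # He initialization: suits the ReLU hidden units used everywhere here.
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        assert self._x is not None, "backward before forward"
        self.gW += self._x.T @ grad_out
        self.gb += grad_out.sum(axis=0)
        return grad_out @ self.W.T

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.gW, self.gb]


class MLP:
    """A stack of Linear layers with ReLU on all but (optionally) the last."""

    def __init__(
        self,
        widths: list[int],
        rng: np.random.Generator,
        relu_last: bool = False,
    ) -> None:
        if len(widths) < 2:
            raise ValueError("widths must list at least input and output size")
        self.layers = [
            Linear(widths[i], widths[i + 1], rng) for i in range(len(widths) - 1)
        ]
        self.relu_last = relu_last
        self._masks: list[np.ndarray | None] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._masks = []
        n = len(self.layers)
        for i, layer in enumerate(self.layers):
            x = layer.forward(x)
            if i < n - 1 or self.relu_last:
                mask = x > 0
                x = x * mask
                self._masks.append(mask)
            else:
                self._masks.append(None)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer, mask in zip(reversed(self.layers), reversed(self._masks)):
            if mask is not None:
                grad_out = grad_out * mask
            grad_out = layer.backward(grad_out)
        return grad_out

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]


class SGDMomentum:
    """Stochastic gradient descent with classical momentum.

    Update: ``v <- momentum * v - lr * g``, ``p <- p + v``.
    """

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-4, momentum: float = 0.9) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be > 0")
        self.params = params
        self.grads = grads
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for p in params]

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def step(self) -> None:
        for p, g, v in zip(self.params, self.grads, self.velocity):
            v *= self.momentum
            v -= self.lr * g
            p += v
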