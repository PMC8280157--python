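"""Minimal fully-connected networks with manual backprop and Adam.

ReLU hidden layers, linear output.  `backward` returns both parameter
gradients and the gradient with respect to the input, which the critic
needs to differentiate the value with respect to the action.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam"]


class MLP:
    """Feed-forward net: sizes = [in, hidden..., out], ReLU hidden."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.sizes = list(sizes)
        self.W = []
        self.b = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.W.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    @property
    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def set_params(self, params: list[np.ndarray]) -> None:
        n = len(self.W)
        self.W = [p.copy() for p in params[:n]]
        self.b = [p.copy() for p in params[n:]]

    def copy(self) -> "MLP":
        other = MLP.__new__(MLP)
        other.sizes = list(self.sizes)
        other.W = [w.copy() for w in self.W]
        other.b = [b.copy() for b in self.b]
        return other

    def forward(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        """Forward pass; if given, ``cache`` collects (input, preact) pairs."""
        h = x
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            if cache is not None:
                cache.append((h, z))
            h = np.maximum(z, 0.0) if i < len(self.W) - 1 else z
        return h

    def backward(
        self, cache: list, dout: np.ndarray
    ) -> tuple[list[np.ndarray], np.ndarray]:
        """Gradients of a scalar loss given d(loss)/d(output).

        Returns (param grads ordered as `params`, d(loss)/d(input)).
        """
        dW = [None] * len(self.W)
        db = [None] * len(self.b)
        grad = dout
        for i in reversed(range(len(self.W))):
            h_in, z = cache[i]
            if i < len(self.W) - 1:
                grad = grad * (z > 0)  # ReLU applied to this layer's output
            dW[i] = h_in.T @ grad
            db[i] = grad.sum(axis=0)
            grad = grad @ self.W[i].T
        return dW + db, grad


class Adam:
    """Adam optimizer over a list of parameter arrays (updated in place)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 3e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
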