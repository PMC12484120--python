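"""First-order optimizers (the five compared in the tuning grid)."""

from __future__ import annotations

import numpy as np


class Optimizer:
    def __init__(self, params, lr: float):
        self.params = list(params)
        if not self.params:
            raise ValueError("optimizer received no parameters")
        self.lr = float(lr)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):  # pragma: no cover - abstract
        raise NotImplementedError


class SGD(Optimizer):
    """Plain stochastic gradient descent (optional classical momentum)."""

    def __init__(self, params, lr: float = 0.001, momentum: float = 0.0):
        super().__init__(params, lr)
        self.momentum = momentum
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            if self.momentum:
                v *= self.momentum
                v += p.grad
                p.data -= self.lr * v
            else:
                p.data -= self.lr * p.grad


class Adam(Optimizer):
    def __init__(self, params, lr: float = 0.001, betas=(0.9, 0.999), eps: float = 1e-8):
        super().__init__(params, lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class Adamax(Optimizer):
    """Adam variant using the infinity norm for the second moment."""

    def __init__(self, params, lr: float = 0.001, betas=(0.9, 0.999), eps: float = 1e-8):
        super().__init__(params, lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._u = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        for p, m, u in zip(self.params, self._m, self._u):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            np.maximum(self.b2 * u, np.abs(p.grad), out=u)
            p.data -= self.lr * (m / bc1) / (u + self.eps)


class Adagrad(Optimizer):
    def __init__(self, params, lr: float = 0.001, eps: float = 1e-10):
        super().__init__(params, lr)
        self.eps = eps
        self._acc = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, acc in zip(self.params, self._acc):
            if p.grad is None:
                continue
            acc += p.grad ** 2
            p.data -= self.lr * p.grad / (np.sqrt(acc) + self.eps)


class RMSprop(Optimizer):
    def __init__(self, params, lr: float = 0.001, rho: float = 0.9, eps: float = 1e-8):
        super().__init__(params, lr)
        self.rho = rho
        self.eps = eps
        self._sq = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, sq in zip(self.params, self._sq):
            if p.grad is None:
                continue
            sq *= self.rho
            sq += (1.0 - self.rho) * p.grad ** 2
            p.data -= self.lr * p.grad / (np.sqrt(sq) + self.eps)


OPTIMIZERS = {
    "sgd": SGD,
    "adam": Adam,
    "adamax": Adamax,
    "adagrad": Adagrad,
    "rmsprop": RMSprop,
}


def make_optimizer(name: str, params, lr: float) -> Optimizer:
    try:
        cls = OPTIMIZERS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(OPTIMIZERS)}")
    return cls(params, lr=lr)
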