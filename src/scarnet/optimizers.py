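"""First-order stochastic optimizers for the surrogate network.

Standard update rules, in-place on a flat list of parameter arrays.  All
optimizers share the interface ``update(params, grads)`` plus a mutable
``lr`` attribute (the training loop applies the per-epoch decay by
rescaling it).  Hyperparameters follow the common framework defaults.
"""

from __future__ import annotations

from typing import Dict, List, Type

import numpy as np

__all__ = ["make_optimizer", "OPTIMIZERS"]


class Optimizer:
    def __init__(self, lr: float):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr = lr
        self._state: Dict[int, dict] = {}
        self._t = 0

    def update(self, params: List[np.ndarray], grads: List[np.ndarray]) -> None:
        self._t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self._apply(self._state.setdefault(i, {}), p, g)

    def _apply(self, s: dict, p: np.ndarray, g: np.ndarray) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    def _apply(self, s, p, g):
        p -= self.lr * g


class RMSprop(Optimizer):
    rho, eps = 0.9, 1e-7

    def _apply(self, s, p, g):
        a = s.setdefault("a", np.zeros_like(p))
        a *= self.rho
        a += (1 - self.rho) * g * g
        p -= self.lr * g / (np.sqrt(a) + self.eps)


class Adam(Optimizer):
    beta1, beta2, eps = 0.9, 0.999, 1e-7

    def _apply(self, s, p, g):
        m = s.setdefault("m", np.zeros_like(p))
        v = s.setdefault("v", np.zeros_like(p))
        m *= self.beta1
        m += (1 - self.beta1) * g
        v *= self.beta2
        v += (1 - self.beta2) * g * g
        mh = m / (1 - self.beta1 ** self._t)
        vh = v / (1 - self.beta2 ** self._t)
        p -= self.lr * mh / (np.sqrt(vh) + self.eps)


class Adamax(Optimizer):
    """Adam variant based on the infinity norm of the gradient history."""

    beta1, beta2, eps = 0.9, 0.999, 1e-7

    def _apply(self, s, p, g):
        m = s.setdefault("m", np.zeros_like(p))
        u = s.setdefault("u", np.zeros_like(p))
        m *= self.beta1
        m += (1 - self.beta1) * g
        np.maximum(self.beta2 * u, np.abs(g), out=u)
        p -= (self.lr / (1 - self.beta1 ** self._t)) * m / (u + self.eps)


class Nadam(Optimizer):
    """Adam with Nesterov momentum."""

    beta1, beta2, eps = 0.9, 0.999, 1e-7

    def _apply(self, s, p, g):
        m = s.setdefault("m", np.zeros_like(p))
        v = s.setdefault("v", np.zeros_like(p))
        m *= self.beta1
        m += (1 - self.beta1) * g
        v *= self.beta2
        v += (1 - self.beta2) * g * g
        mh = m / (1 - self.beta1 ** (self._t + 1))
        vh = v / (1 - self.beta2 ** self._t)
        nesterov = self.beta1 * mh + (1 - self.beta1) * g / (1 - self.beta1 ** self._t)
        p -= self.lr * nesterov / (np.sqrt(vh) + self.eps)


class Adagrad(Optimizer):
    eps = 1e-7

    def _apply(self, s, p, g):
        a = s.setdefault("a", np.full_like(p, 0.1))
        a += g * g
        p -= self.lr * g / (np.sqrt(a) + self.eps)


class Adadelta(Optimizer):
    rho, eps = 0.95, 1e-7

    def _apply(self, s, p, g):
        a = s.setdefault("a", np.zeros_like(p))
        d = s.setdefault("d", np.zeros_like(p))
        a *= self.rho
        a += (1 - self.rho) * g * g
        step = np.sqrt(d + self.eps) / np.sqrt(a + self.eps) * g
        d *= self.rho
        d += (1 - self.rho) * step * step
        p -= self.lr * step


class Ftrl(Optimizer):
    """FTRL-proximal with no L1/L2 regularization (plain follow-the-leader)."""

    beta = 1.0

    def _apply(self, s, p, g):
        n = s.setdefault("n", np.full_like(p, 0.1))
        z = s.setdefault("z", np.zeros_like(p))
        n_new = n + g * g
        sigma = (np.sqrt(n_new) - np.sqrt(n)) / self.lr
        z += g - sigma * p
        n[:] = n_new
        p[:] = -z / ((self.beta + np.sqrt(n)) / self.lr)


OPTIMIZERS: Dict[str, Type[Optimizer]] = {
    "sgd": SGD,
    "rmsprop": RMSprop,
    "adam": Adam,
    "adamax": Adamax,
    "nadam": Nadam,
    "adagrad": Adagrad,
    "adadelta": Adadelta,
    "ftrl": Ftrl,
}


def make_optimizer(name: str, lr: float) -> Optimizer:
    try:
        return OPTIMIZERS[name.lower()](lr)
    except KeyError:
        raise ValueError(
            f"unknown optimizer {name!r}; choose from {sorted(OPTIMIZERS)}"
        ) from None
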