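"""SGD (with momentum / weight decay) and Adam over named parameter sets.

Optimizers take *named* parameters so that freezing is expressed as a set of
layer-name prefixes: a frozen parameter is simply never stepped, which
together with broadcast skipping guarantees bit-identity of frozen layers.
"""

from __future__ import annotations

import numpy as np

from .layers import Parameter

__all__ = ["SGD", "Adam"]


def _is_frozen(name: str, frozen: set[str] | frozenset[str]) -> bool:
    return any(name == f or name.startswith(f + ".") for f in frozen)


class SGD:
    def __init__(self, named_params: dict[str, Parameter], lr: float,
                 momentum: float = 0.9, weight_decay: float = 0.0,
                 frozen: set[str] | frozenset[str] = frozenset()):
        self.params = {n: p for n, p in named_params.items()
                       if not _is_frozen(n, frozen)}
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._vel = {n: np.zeros_like(p.data) for n, p in self.params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def step(self) -> None:
        for n, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v = self._vel[n]
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v


class Adam:
    def __init__(self, named_params: dict[str, Parameter], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0,
                 frozen: set[str] | frozenset[str] = frozenset()):
        self.params = {n: p for n, p in named_params.items()
                       if not _is_frozen(n, frozen)}
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self._m = {n: np.zeros_like(p.data) for n, p in self.params.items()}
        self._v = {n: np.zeros_like(p.data) for n, p in self.params.items()}
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        for n, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self._m[n] = b1 * self._m[n] + (1 - b1) * g
            self._v[n] = b2 * self._v[n] + (1 - b2) * g * g
            mhat = self._m[n] / (1 - b1 ** self._t)
            vhat = self._v[n] / (1 - b2 ** self._t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
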