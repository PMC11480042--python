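"""Stochastic optimizers operating on lists of autodiff tensors."""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor


class RMSProp:
    """RMSProp with the usual leaky average of squared gradients.

    Parameters follow the common convention: decay ``rho`` 0.9 and a small
    ``eps`` inside the square root for numerical safety.
    """

    def __init__(self, params: list[Tensor], lr: float = 0.003, rho: float = 0.9, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self._acc = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        for p, acc in zip(self.params, self._acc):
            if p.grad is None:
                continue
            acc *= self.rho
            acc += (1.0 - self.rho) * p.grad**2
            p.value -= self.lr * p.grad / (np.sqrt(acc) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class Adam:
    def __init__(
        self,
        params: list[Tensor],
        lr: float = 3e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad**2
            mhat = m / (1.0 - b1**self._t)
            vhat = v / (1.0 - b2**self._t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
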