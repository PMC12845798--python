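"""Nadam optimiser (Adam with Nesterov momentum)."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Nadam"]


class Nadam:
    """Nadam: Adam updates with a Nesterov look-ahead on the first moment.

    Update at step t (per parameter, elementwise)::

        m_t = b1*m + (1-b1)*g        v_t = b2*v + (1-b2)*g^2
        m_hat = m_t/(1-b1^t)         v_hat = v_t/(1-b2^t)
        theta -= lr * (b1*m_hat + (1-b1)*g/(1-b1^t)) / (sqrt(v_hat)+eps)

    ``lr`` is mutable so a plateau scheduler can halve it mid-run.
    """

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params: list[Tensor] = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self._t
        c2 = 1.0 - b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            m_hat = m / c1
            v_hat = v / c2
            update = (b1 * m_hat + (1.0 - b1) * g / c1) / (np.sqrt(v_hat) + self.eps)
            p.data -= self.lr * update

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
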