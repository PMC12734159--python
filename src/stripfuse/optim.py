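"""First-order optimisers: AdamW (default), Adam, RMSprop and SGD."""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter

__all__ = ["AdamW", "RMSprop", "SGD"]


class AdamW:
    """Adam with decoupled weight decay (the default training optimiser).

    Update per step t:
        m <- b1 m + (1-b1) g;  v <- b2 v + (1-b2) g^2
        w <- w - lr * ( m_hat / (sqrt(v_hat) + eps) + weight_decay * w )

    With ``decoupled=False`` the decay is folded into the gradient instead
    (classic Adam with an L2 penalty).
    """

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-4,
        decoupled: bool = True,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decoupled = decoupled
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and not self.decoupled:
                g = g + self.weight_decay * p.data
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and self.decoupled:
                update = update + self.weight_decay * p.data
            p.data = p.data - self.lr * update


class RMSprop:
    def __init__(self, params, lr=1e-3, alpha=0.99, eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.alpha, self.eps, self.weight_decay = lr, alpha, eps, weight_decay
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.alpha
            v += (1.0 - self.alpha) * g * g
            p.data = p.data - self.lr * g / (np.sqrt(v) + self.eps)


class SGD:
    def __init__(self, params, lr=1e-2, momentum=0.9, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, m in zip(self.params, self._m):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.momentum
            m += g
            p.data = p.data - self.lr * m
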