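"""Adam optimizer with coupled L2 weight decay."""

from __future__ import annotations

import numpy as np

from .autograd import Parameter

__all__ = ["Adam"]


class Adam:
    """Adam as commonly implemented: decay is added to the raw gradient
    before the moment updates (coupled L2, not AdamW)."""

    def __init__(self, params, lr: float = 0.02,
                 betas: tuple[float, float] = (0.89, 0.999),
                 eps: float = 1e-8, weight_decay: float = 5e-4):
        self.params: list[Parameter] = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
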