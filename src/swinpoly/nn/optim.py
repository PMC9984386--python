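"""Adam optimizer and the cosine learning-rate schedule used for training."""

from __future__ import annotations

import numpy as np

from .layers import Parameter

__all__ = ["Adam", "cosine_lr"]


class Adam:
    """Adam with bias correction (Kingma & Ba). Defaults: β1=0.9, β2=0.999."""

    def __init__(self, params: list[Parameter], lr: float = 2e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def cosine_lr(epoch: int, total_epochs: int, lr_init: float, lr_final: float) -> float:
    """Cosine annealing from lr_init (epoch 0) to lr_final (last epoch)."""
    if total_epochs <= 1:
        return lr_init
    frac = epoch / (total_epochs - 1)
    return lr_final + 0.5 * (lr_init - lr_final) * (1.0 + np.cos(np.pi * frac))
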