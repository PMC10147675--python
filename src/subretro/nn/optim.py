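"""Adam optimizer and the Noam warmup learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class Adam:
    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.998),
        eps: float = 1e-9,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self._m[i] = b1 * self._m[i] + (1 - b1) * p.grad
            self._v[i] = b2 * self._v[i] + (1 - b2) * p.grad ** 2
            m_hat = self._m[i] / (1 - b1 ** self.t)
            v_hat = self._v[i] / (1 - b2 ** self.t)
            p.data -= lr * m_hat / (np.sqrt(v_hat) + self.eps)


def noam_lr(step: int, d_model: int, warmup: int, scale: float = 2.0) -> float:
    """Noam schedule: linear warmup then inverse-sqrt decay."""
    step = max(step, 1)
    return scale * d_model ** -0.5 * min(step ** -0.5, step * warmup ** -1.5)
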