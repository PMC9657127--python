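"""Optimisers and learning-rate schedules.

RAdam (rectified Adam, Liu et al. 2020) is the training optimiser: Adam
whose adaptive step is switched off while the variance estimate is still
untrustworthy (small t), then rectified by the variance of the
exponential moving average. The step-decay schedule multiplies the
learning rate by a fixed factor every ``step_size`` epochs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["RAdam", "StepLR"]


class RAdam:
    def __init__(self, parameters, lr=1e-4, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(parameters)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self.rho_inf = 2.0 / (1.0 - self.beta2) - 1.0

    def step(self):
        self.t += 1
        t = self.t
        b1, b2 = self.beta1, self.beta2
        b1t, b2t = b1**t, b2**t
        rho_t = self.rho_inf - 2.0 * t * b2t / (1.0 - b2t)
        if rho_t > 4.0:
            rect = np.sqrt(
                ((rho_t - 4.0) * (rho_t - 2.0) * self.rho_inf)
                / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho_t)
            )
        else:
            rect = None
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            m_hat = m / (1.0 - b1t)
            if rect is not None:
                v_hat = np.sqrt(v / (1.0 - b2t)) + self.eps
                p.data = p.data - self.lr * rect * m_hat / v_hat
            else:  # un-rectified warmup: plain SGD with momentum-corrected mean
                p.data = p.data - self.lr * m_hat

    def zero_grad(self):
        for p in self.params:
            p.grad = np.zeros_like(p.data)


class StepLR:
    """lr(epoch) = lr0 * gamma ** (epoch // step_size), epochs counted from 0."""

    def __init__(self, optimizer: RAdam, step_size: int = 20, gamma: float = 0.1):
        self.optimizer = optimizer
        self.lr0 = optimizer.lr
        self.step_size = step_size
        self.gamma = gamma

    def lr_at(self, epoch: int) -> float:
        return self.lr0 * self.gamma ** (epoch // self.step_size)

    def set_epoch(self, epoch: int):
        self.optimizer.lr = self.lr_at(epoch)
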