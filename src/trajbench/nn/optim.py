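"""First-order optimizers for the autodiff engine."""

from __future__ import annotations

import numpy as np

from trajbench.nn.autograd import Tensor, DTYPE


class Optimizer:
    def __init__(self, params: list[Tensor], lr: float):
        self.params = params
        self.lr = lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        raise NotImplementedError


class Adam(Optimizer):
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)


class Adadelta(Optimizer):
    def __init__(self, params, lr=1.0, rho=0.95, eps=1e-6):
        super().__init__(params, lr)
        self.rho, self.eps = rho, eps
        self.Eg = [np.zeros_like(p.data) for p in params]
        self.Ed = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        rho, eps = self.rho, self.eps
        for p, Eg, Ed in zip(self.params, self.Eg, self.Ed):
            if p.grad is None:
                continue
            g = p.grad
            Eg *= rho
            Eg += (1 - rho) * g * g
            delta = np.sqrt(Ed + eps) / np.sqrt(Eg + eps) * g
            Ed *= rho
            Ed += (1 - rho) * delta * delta
            p.data -= (self.lr * delta).astype(DTYPE)
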