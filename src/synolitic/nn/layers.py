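"""Parameterised building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: recursively collects trainable tensors."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p.data = s.copy()


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias=True):
        scale = np.sqrt(2.0 / (in_dim + out_dim))
        self.weight = Tensor(rng.normal(0.0, scale, (in_dim, out_dim)), True)
        self.bias = Tensor(np.zeros((1, out_dim)), True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = ag.matmul(x, self.weight)
        return out if self.bias is None else ag.add(out, self.bias)


class MLP(Module):
    """Two-layer perceptron with ReLU, used as the edge encoder."""

    def __init__(self, in_dim, hidden, out_dim, rng):
        self.fc1 = Linear(in_dim, hidden, rng)
        self.fc2 = Linear(hidden, out_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(ag.relu(self.fc1(x)))


class BatchNorm(Module):
    """Batch normalisation over rows; evaluation uses running statistics."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, dim)), True)
        self.beta = Tensor(np.zeros((1, dim)), True)
        self.running_mean = np.zeros((1, dim))
        self.running_var = np.ones((1, dim))
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = ag.mean(x, axis=0, keepdims=True)
            centered = ag.add(x, ag.mul(mu, ag.constant(-1.0)))
            var = ag.mean(ag.mul(centered, centered), axis=0, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data
            )
            n = x.data.shape[0]
            unbiased = var.data * (n / max(n - 1, 1))
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * unbiased
            )
            denom = ag.sqrt(ag.add(var, ag.constant(self.eps)))
            xhat = ag.div(centered, denom)
        else:
            xhat = ag.mul(
                ag.add(x, ag.constant(-self.running_mean)),
                ag.constant(1.0 / np.sqrt(self.running_var + self.eps)),
            )
        return ag.add(ag.mul(xhat, self.gamma), self.beta)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return ag.mul(x, ag.constant(mask))


class Adam:
    """Adam with global-norm gradient clipping (stabilises small-batch
    training on imbalanced folds)."""

    def __init__(self, params: list[Tensor], lr: float, betas=(0.9, 0.999),
                 eps=1e-8, clip_norm: float = 5.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((p.grad**2).sum())
                                for p in self.params if p.grad is not None))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                for p in self.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
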