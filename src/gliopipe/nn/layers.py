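"""Parameterized layers and the Adam optimizer for the autodiff engine."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv3d

__all__ = ["Module", "Conv3d", "Linear", "Adam"]


class Module:
    """Minimal parameter container with recursive discovery."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []

        def collect(value) -> None:
            if isinstance(value, Tensor):
                if value.requires_grad:
                    params.append(value)
            elif isinstance(value, Module):
                for sub in vars(value).values():
                    collect(sub)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    collect(item)

        for value in vars(self).values():
            collect(value)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError(f"state has {len(state)} arrays, model has {len(params)} parameters")
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError(f"parameter shape mismatch: {p.data.shape} vs {arr.shape}")
            p.data = arr.copy()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Conv3d(Module):
    """3D convolution with cubic kernel, He-normal initialization."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 stride: int = 1, padding: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel**3
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.standard_normal((out_channels, in_channels, kernel, kernel, kernel)) * scale,
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features)
        self.weight = Tensor(rng.standard_normal((in_features, out_features)) * scale, requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
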