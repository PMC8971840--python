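"""Module / optimizer layer on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor, batchnorm, conv3d, linear, relu

__all__ = ["Module", "Conv3d", "BatchNorm3d", "Linear", "ReLU", "Sequential", "Adam"]


class Module:
    """Minimal module: recursive parameter discovery and train/eval mode."""

    training: bool = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        collect(self)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]

        def collect(obj):
            if isinstance(obj, Module):
                mods.append(obj)
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        for v in vars(self).values():
            collect(v)
        return mods

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, bias: bool = True, rng=None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k**3
        self.w = Parameter(rng.normal(0, np.sqrt(2.0 / fan_in), (c_out, c_in, k, k, k)))
        self.b = Parameter(np.zeros(c_out)) if bias else None
        self.stride = stride
        self.pad = k // 2 if pad is None else pad

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class BatchNorm3d(Module):
    def __init__(self, c: int, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        return batchnorm(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum,
        )


class Linear(Module):
    def __init__(self, c_in: int, c_out: int, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = Parameter(rng.normal(0, np.sqrt(1.0 / c_in), (c_in, c_out)))
        self.b = Parameter(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        return linear(x, self.w, self.b)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return relu(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam with bias correction."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
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
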