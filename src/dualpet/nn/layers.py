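"""Neural-network layers built on the autodiff tensor engine."""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    """Base class: parameter collection and train/eval mode propagation."""

    def __init__(self):
        self.training = True

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield val
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list[Tensor]:
        params = []
        for val in vars(self).values():
            if isinstance(val, Tensor) and val.requires_grad:
                params.append(val)
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        for child in self._children():
            params.extend(child.parameters())
        return params

    def train(self):
        self.training = True
        for child in self._children():
            child.train()
        return self

    def eval(self):
        self.training = False
        for child in self._children():
            child.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}

        def walk(mod, prefix):
            for name, val in vars(mod).items():
                if isinstance(val, Tensor):
                    out[prefix + name] = val.data.copy()
                elif isinstance(val, Module):
                    walk(val, prefix + name + ".")
                elif isinstance(val, (list, tuple)):
                    for i, item in enumerate(val):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{name}.{i}.")
                        elif isinstance(item, Tensor):
                            out[f"{prefix}{name}.{i}"] = item.data.copy()

        walk(self, "")
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        def walk(mod, prefix):
            for name, val in vars(mod).items():
                if isinstance(val, Tensor):
                    val.data[...] = state[prefix + name]
                elif isinstance(val, Module):
                    walk(val, prefix + name + ".")
                elif isinstance(val, (list, tuple)):
                    for i, item in enumerate(val):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{name}.{i}.")
                        elif isinstance(item, Tensor):
                            item.data[...] = state[f"{prefix}{name}.{i}"]

        walk(self, "")

    def count_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Conv2d(Module):
    """Stride-1 convolution with 'same' zero padding (He-initialised)."""

    def __init__(self, in_ch: int, out_ch: int, kh: int, kw: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        fan_in = in_ch * kh * kw
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, std, (out_ch, in_ch, kh, kw)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, pad="same")


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(n_ch), requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = T.mean_axes(x, (0, 2, 3), keepdims=True)
            xc = T.sub(x, mu)
            var = T.mean_axes(T.square(xc), (0, 2, 3), keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbias = n / max(n - 1, 1)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel() * unbias)
            inv = T.div(Tensor(1.0), T.sqrt(T.add(var, Tensor(self.eps))))
            xn = T.mul(xc, inv)
        else:
            mu = self.running_mean[None, :, None, None]
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xn = T.mul(T.sub(x, Tensor(mu)), Tensor(inv[None, :, None, None]))
        g = T.reshape(self.gamma, (1, -1, 1, 1))
        b = T.reshape(self.beta, (1, -1, 1, 1))
        return T.add(T.mul(xn, g), b)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / in_f)
        self.weight = Tensor(rng.normal(0.0, std, (in_f, out_f)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_f), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return T.add(T.matmul(x, self.weight), T.reshape(self.bias, (1, -1)))


class ConvBlock(Module):
    """Convolution + batch normalisation + ReLU, spatial size preserved."""

    def __init__(self, in_ch: int, out_ch: int, kh: int, kw: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kh, kw, rng)
        self.bn = BatchNorm2d(out_ch)

    def __call__(self, x: Tensor) -> Tensor:
        return T.relu(self.bn(self.conv(x)))


class Adam:
    """Adam optimiser (the community default for this training setup)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
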