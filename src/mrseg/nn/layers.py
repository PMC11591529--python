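"""Layer/module abstractions over the Tensor engine."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "GroupNorm",
    "ReLU",
    "Sigmoid",
    "MaxPool2d",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class; submodules and parameters are discovered via __dict__."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{name}.{i}", item

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- flat state (for checkpoints) ---------------------------------------
    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = ""):
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Module):
                yield from v.named_buffers(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{name}.{i}.")
            elif isinstance(v, np.ndarray) and k.startswith("running_"):
                yield name, v

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, value in state.items():
            if name in params:
                params[name].data = np.asarray(value, dtype=np.float32).reshape(
                    params[name].data.shape
                )
            elif name in buffers:
                buffers[name][...] = value
            else:
                raise KeyError(f"unknown state entry {name!r}")


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
    ):
        super().__init__()
        k = kernel_size
        fan_in = in_channels * k * k
        self.weight = Parameter(_he_normal(rng, (out_channels, in_channels, k, k), fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, in_channels: int, out_channels: int, stride: int, rng: np.random.Generator):
        super().__init__()
        fan_in = in_channels * stride * stride
        self.weight = Parameter(
            _he_normal(rng, (in_channels, out_channels, stride, stride), fan_in)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32))
        self.stride = stride

    def forward(self, x):
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        C = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (
                mu.data.reshape(C) - self.running_mean
            )
            self.running_var += self.momentum * (var.data.reshape(C) - self.running_var)
            xn = (x - mu) * (var + self.eps).pow(-0.5)
        else:
            mu = self.running_mean.reshape(1, C, 1, 1)
            std = np.sqrt(self.running_var + self.eps).reshape(1, C, 1, 1)
            xn = (x - Tensor(mu)) * Tensor(1.0 / std)
        return xn * self.weight.reshape(1, C, 1, 1) + self.bias.reshape(1, C, 1, 1)


class GroupNorm(Module):
    def __init__(self, num_groups: int, channels: int, eps: float = 1e-5):
        super().__init__()
        if channels % num_groups:
            raise ValueError("channels must divide evenly into groups")
        self.num_groups = num_groups
        self.weight = Parameter(np.ones(channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))
        self.eps = eps

    def forward(self, x):
        B, C, H, W = x.shape
        G = self.num_groups
        xg = x.reshape(B, G, (C // G) * H * W)
        mu = xg.mean(axis=2, keepdims=True)
        var = ((xg - mu) * (xg - mu)).mean(axis=2, keepdims=True)
        xn = ((xg - mu) * (var + self.eps).pow(-0.5)).reshape(B, C, H, W)
        return xn * self.weight.reshape(1, C, 1, 1) + self.bias.reshape(1, C, 1, 1)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return F.max_pool2d(x, self.kernel, self.stride, self.padding)
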