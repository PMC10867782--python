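"""Network building blocks on top of the autodiff core.

Weight initialisation is Xavier/Glorot throughout, drawn from an explicit
``numpy.random.Generator`` so that network construction is reproducible.
Offset-prediction convolutions inside deformable blocks are zero-initialised,
so an untrained deformable convolution reduces exactly to a standard one.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import (Tensor, conv2d, conv_transpose2d, deform_conv2d)

__all__ = [
    "Module", "Parameter", "Sequential", "Conv2d", "ConvTranspose2d",
    "DeformConv2d", "BatchNorm2d", "Linear", "xavier_uniform",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def xavier_uniform(shape: tuple, rng: np.random.Generator,
                   fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Composable parameter container with a torch-like surface."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._modules: dict[str, "Module"] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for k, p in self._params.items():
            yield prefix + k, p
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for k, v in self._buffers.items():
            yield prefix + k, v
        for k, m in self._modules.items():
            yield from m.named_buffers(prefix + k + ".")

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: p.data.copy() for k, p in self.named_parameters()}
        state.update({"buffer:" + k: v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for k, v in state.items():
            if k.startswith("buffer:"):
                buf = buffers[k[len("buffer:"):]]
                buf[...] = v
            else:
                if params[k].data.shape != v.shape:
                    raise ValueError(f"shape mismatch for {k}")
                params[k].data[...] = v

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"l{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None, bias: bool = True,
                 zero_init: bool = False):
        super().__init__()
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        fan_in, fan_out = cin * k * k, cout * k * k
        if zero_init:
            w = np.zeros((cout, cin, k, k))
        else:
            w = xavier_uniform((cout, cin, k, k), rng, fan_in, fan_out)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class ConvTranspose2d(Module):
    """k=4, stride=2, pad=1 doubles spatial resolution exactly."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 k: int = 4, stride: int = 2, pad: int = 1, bias: bool = True):
        super().__init__()
        self.stride, self.pad = stride, pad
        fan_in, fan_out = cin * k * k, cout * k * k
        self.weight = Parameter(xavier_uniform((cin, cout, k, k), rng, fan_in, fan_out))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias,
                                stride=self.stride, pad=self.pad)


class DeformConv2d(Module):
    """Deformable convolution with its learned offset-prediction layer.

    The offset head is a standard convolution (zero-initialised) over the
    same input, emitting 2 displacement channels per kernel tap.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None, bias: bool = True):
        super().__init__()
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        self.k = k
        self.offset_conv = Conv2d(cin, 2 * k * k, k, rng, stride=stride,
                                  pad=self.pad, zero_init=True)
        fan_in, fan_out = cin * k * k, cout * k * k
        self.weight = Parameter(xavier_uniform((cout, cin, k, k), rng, fan_in, fan_out))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x: Tensor, offsets: Tensor | None = None) -> Tensor:
        if offsets is None:
            offsets = self.offset_conv(x)
        return deform_conv2d(x, offsets, self.weight, self.bias,
                             stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self._buffers["running_mean"] = np.zeros(channels)
        self._buffers["running_var"] = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            self._buffers["running_mean"] *= (1 - self.momentum)
            self._buffers["running_mean"] += self.momentum * mu.data.ravel()
            self._buffers["running_var"] *= (1 - self.momentum)
            self._buffers["running_var"] += self.momentum * var.data.ravel()
        else:
            mu = Tensor(self._buffers["running_mean"][None, :, None, None])
            var = Tensor(self._buffers["running_var"][None, :, None, None])
        xhat = (x - mu) * (var + self.eps) ** -0.5
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class Linear(Module):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Parameter(xavier_uniform((fin, fout), rng, fin, fout))
        self.bias = Parameter(np.zeros(fout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out
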