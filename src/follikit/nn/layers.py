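"""Neural-network layers built on the autodiff Tensor."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d, conv_transpose2x2, max_pool2x2


class Module:
    """Base class: tracks parameters and sub-modules via attribute assignment."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + name: p for name, p in self._params.items()}
        for mname, m in self._modules.items():
            out.update(m.named_parameters(prefix + mname + "."))
        return out

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters().items()}
        for name, m in self._named_modules().items():
            if isinstance(m, BatchNorm2d):
                state[name + ".running_mean"] = m.running_mean.copy()
                state[name + ".running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.named_parameters()
        for name, p in params.items():
            p.data = np.asarray(state[name], dtype=np.float64).copy()
        for name, m in self._named_modules().items():
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(state[name + ".running_mean"]).copy()
                m.running_var = np.asarray(state[name + ".running_var"]).copy()

    def _named_modules(self, prefix: str = "") -> dict[str, "Module"]:
        out: dict[str, "Module"] = {}
        for name, m in self._modules.items():
            out[prefix + name] = m
            out.update(m._named_modules(prefix + name + "."))
        return out

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def kaiming_weight(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int) -> Tensor:
    """He-style fan-in scaled normal init."""
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)


class Conv2d(Module):
    """Stride-1 'same' or 'valid' 2-D convolution (supports 1-D factorized kernels)."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel_size: tuple[int, int], rng: np.random.Generator,
                 padding: tuple[int, int] | str = "same", bias: bool = True):
        super().__init__()
        kh, kw = kernel_size
        if padding == "same":
            padding = ((kh - 1) // 2, (kw - 1) // 2)
        self.padding = padding
        fan_in = in_channels * kh * kw
        self.weight = kaiming_weight(rng, (out_channels, in_channels, kh, kw), fan_in)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class ConvTranspose2x2(Module):
    """Stride-2 transposed conv with 2x2 kernel: doubles spatial dims."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        fan_in = in_channels  # each output pixel sees one input pixel per channel
        self.weight = kaiming_weight(rng, (in_channels, out_channels, 2, 2), fan_in)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_var = (1 - m) * self.running_var + m * unbiased
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mu) * (var + self.eps).pow(-0.5)
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class MaxPool2x2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return max_pool2x2(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"m{i}", layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()
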