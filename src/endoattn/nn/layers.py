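"""Layer/module system: parameter registration, modes, (de)serialization."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .autograd import Parameter, Tensor

__all__ = [
    "Module", "ModuleList", "Conv2d", "SeparableConv2d", "BatchNorm2d",
    "MaxPool2d", "Linear", "initialize_parameters",
]


class Module:
    """Base class; submodules and parameters are discovered via __dict__."""

    def __init__(self):
        self.training = True

    # -- traversal -----------------------------------------------------------
    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    # -- modes / gradients ---------------------------------------------------
    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- state ---------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, value in vars(self).items():
            # ndarray attributes are persistent buffers (e.g. BN running
            # stats) unless marked private with a leading underscore
            if isinstance(value, np.ndarray) and not name.startswith("_"):
                state[name] = value.copy()
        for name, child in self._children():
            for key, val in child.state_dict().items():
                state[f"{name}.{key}"] = val
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = self._named_buffers()
        for key, val in state.items():
            if key in params:
                params[key].data = np.array(val, dtype=np.float64)
            elif key in buffers:
                owner, attr = buffers[key]
                getattr(owner, attr)[...] = val
            else:
                raise KeyError(f"unknown state entry {key!r}")

    def _named_buffers(self, prefix: str = ""):
        out = {}
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray) and not name.startswith("_"):
                out[prefix + name] = (self, name)
        for name, child in self._children():
            out.update(child._named_buffers(prefix + name + "."))
        return out

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, items=()):
        super().__init__()
        self.items = list(items)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 bias: bool = True):
        super().__init__()
        self.stride, self.padding, self.groups = stride, padding, groups
        self.weight = Parameter(
            np.zeros((out_channels, in_channels // groups, kernel, kernel)),
            init_kind="conv_weight")
        self.bias = Parameter(np.zeros(out_channels), init_kind="bias") \
            if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride,
                        self.padding, self.groups)


class SeparableConv2d(Module):
    """Depthwise 3x3 convolution followed by a pointwise 1x1 convolution."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel: int = 3, padding: int = 1):
        super().__init__()
        self.depthwise = Conv2d(in_channels, in_channels, kernel,
                                padding=padding, groups=in_channels, bias=False)
        self.pointwise = Conv2d(in_channels, out_channels, 1, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        return self.pointwise(self.depthwise(x))


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Parameter(np.ones(channels), init_kind="bn_gamma")
        self.beta = Parameter(np.zeros(channels), init_kind="bn_beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, self.training,
                              self.momentum, self.eps)


class MaxPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return F.max_pool2d(x, self.kernel, self.stride, self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int):
        super().__init__()
        self.weight = Parameter(np.zeros((out_features, in_features)),
                                init_kind="linear_weight")
        self.bias = Parameter(np.zeros(out_features), init_kind="bias")

    def forward(self, x: Tensor) -> Tensor:
        return F.linear(x, self.weight, self.bias)


def initialize_parameters(module: Module, seed: int) -> Module:
    """He-normal initialization, deterministic in (architecture, seed).

    Parameters are visited in registration order, so two structurally
    identical networks initialized with the same seed share weights exactly.
    """
    rng = np.random.default_rng(seed)
    for _, p in module.named_parameters():
        if p.init_kind == "conv_weight":
            fan_in = int(np.prod(p.data.shape[1:]))
            p.data = rng.normal(0.0, np.sqrt(2.0 / fan_in), p.data.shape)
        elif p.init_kind == "linear_weight":
            fan_in = p.data.shape[1]
            p.data = rng.normal(0.0, np.sqrt(2.0 / fan_in), p.data.shape)
        elif p.init_kind == "bn_gamma":
            p.data = np.ones_like(p.data)
        else:  # biases and BN beta
            p.data = np.zeros_like(p.data)
    return module
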