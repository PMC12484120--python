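"""Module system and the layers the network is assembled from."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Parameter, Tensor

# Module-level RNG for parameter initialization; reseed with manual_seed().
_rng = np.random.default_rng(0)

DEFAULT_DTYPE = np.float32


def manual_seed(seed: int) -> None:
    """Reseed the parameter-initialization stream (deterministic builds)."""
    global _rng
    _rng = np.random.default_rng(seed)


def _he_normal(shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return _rng.normal(0.0, std, size=shape).astype(DEFAULT_DTYPE)


class Module:
    """Base class: attribute-based parameter/submodule discovery."""

    def __init__(self):
        self.training = True
        self._buffers: dict[str, np.ndarray] = {}

    # -- traversal ---------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if name == "_buffers":
                continue
            if isinstance(value, Parameter):
                yield prefix + name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix + name + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if name == "_buffers":
                for bname, buf in value.items():
                    yield prefix + bname, buf
            elif isinstance(value, Module):
                yield from value.named_buffers(prefix + name + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{name}.{i}.")

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value

    # -- modes -------------------------------------------------------------
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

    def astype(self, dtype):
        """Cast all parameters and buffers in place (e.g. np.float64)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        for m in self.modules():
            for k in m._buffers:
                m._buffers[k] = m._buffers[k].astype(dtype)
        return self

    # -- (de)serialization --------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state["buffer:" + name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buf_map = {name: (mod, key) for name, mod, key in self._iter_buffer_slots()}
        for name, value in state.items():
            if name.startswith("buffer:"):
                bname = name[len("buffer:"):]
                if bname not in buf_map:
                    raise KeyError(f"unknown buffer {bname!r} in state dict")
                mod, key = buf_map[bname]
                mod._buffers[key] = np.array(value, dtype=mod._buffers[key].dtype)
            else:
                if name not in params:
                    raise KeyError(f"unknown parameter {name!r} in state dict")
                p = params[name]
                if p.data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name!r}: "
                                     f"{p.data.shape} vs {value.shape}")
                p.data = np.array(value, dtype=p.data.dtype)

    def _iter_buffer_slots(self, prefix: str = ""):
        for name, value in vars(self).items():
            if name == "_buffers":
                for bname in value:
                    yield prefix + bname, self, bname
            elif isinstance(value, Module):
                yield from value._iter_buffer_slots(prefix + name + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._iter_buffer_slots(f"{prefix}{name}.{i}.")

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Stride-1, zero-padded ('same') 2-D convolution with square dilation."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 dilation: int = 1, bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.dilation = dilation
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(_he_normal(
            (out_channels, in_channels, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=DEFAULT_DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, dilation=self.dilation)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_he_normal((out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=DEFAULT_DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features, dtype=DEFAULT_DTYPE))
        self.bias = Parameter(np.zeros(num_features, dtype=DEFAULT_DTYPE))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=DEFAULT_DTYPE))
        self.register_buffer("running_var", np.ones(num_features, dtype=DEFAULT_DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm(x, self.weight, self.bias,
                            self._buffers["running_mean"], self._buffers["running_var"],
                            training=self.training, momentum=self.momentum, eps=self.eps)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ConvBlock(Module):
    """Convolution -> batch norm -> ReLU (norm/activation optional)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 dilation: int = 1, norm: bool = True, act: bool = True):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, kernel_size, dilation=dilation)
        self.norm = BatchNorm2d(out_channels) if norm else None
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv(x)
        if self.norm is not None:
            y = self.norm(y)
        if self.act:
            y = F.relu(y)
        return y


class DoubleConv(Module):
    """Two stacked 3x3 ConvBlocks — the plain U-Net stage."""

    def __init__(self, in_channels: int, out_channels: int):
        super().__init__()
        self.block1 = ConvBlock(in_channels, out_channels, 3)
        self.block2 = ConvBlock(out_channels, out_channels, 3)

    def forward(self, x: Tensor) -> Tensor:
        return self.block2(self.block1(x))
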