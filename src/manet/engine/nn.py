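"""Minimal layer/module system over the autodiff engine.

Weight initialization draws from a module-level generator so that a whole
network can be built reproducibly under :func:`seeded_init`.
"""

from __future__ import annotations

import contextlib
from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Tensor

_INIT_RNG = np.random.default_rng(0)


@contextlib.contextmanager
def seeded_init(seed: int):
    """Route all weight initialization inside the block through one generator."""
    global _INIT_RNG
    prev = _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)
    try:
        yield
    finally:
        _INIT_RNG = prev


def _init_rng() -> np.random.Generator:
    return _INIT_RNG


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal -----------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    # -- mode ----------------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- (de)serialization ---------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        for name, p in own.items():
            if name not in state:
                raise KeyError(f"missing parameter '{name}' in state dict")
            if state[name].shape != p.data.shape:
                raise ValueError(f"shape mismatch for '{name}'")
            p.data = np.asarray(state[name], dtype=p.data.dtype).copy()
        for name, b in self.named_buffers():
            if name in state:
                b[...] = state[name]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._items: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, mod: Module):
        self._modules[str(len(self._items))] = mod
        self._items.append(mod)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self._items = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def forward(self, x: Tensor) -> Tensor:
        for m in self._items:
            x = m(x)
        return x


class Conv2d(Module):
    """Same-padded 2-D convolution (odd kernels) with He-normal init."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, *,
                 stride: int = 1, dilation: int = 1, bias: bool = True,
                 padding: int | str = "same"):
        super().__init__()
        if out_channels < 1 or in_channels < 1:
            raise ValueError("channel counts must be positive")
        k = kernel_size
        if padding == "same":
            padding = dilation * (k - 1) // 2
        self.stride, self.dilation, self.padding = stride, dilation, padding
        fan_in = in_channels * k * k
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(_init_rng().normal(0.0, std, (out_channels, in_channels, k, k)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        dilation=self.dilation, padding=self.padding)


class ConvTranspose2d(Module):
    """Stride-2 transposed convolution that exactly doubles H and W."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 *, bias: bool = True):
        super().__init__()
        k = kernel_size
        if k == 3:
            self.padding, self.output_padding = 1, 1
        elif k == 2:
            self.padding, self.output_padding = 0, 0
        else:
            raise ValueError("kernel_size must be 2 or 3 for stride-2 upsampling")
        fan_in = in_channels * k * k
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(_init_rng().normal(0.0, std, (in_channels, out_channels, k, k)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.weight, self.bias, stride=2,
                                  padding=self.padding, output_padding=self.output_padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, *, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, training=self.training,
                            momentum=self.momentum, eps=self.eps)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class MaxPool2d(Module):
    def __init__(self, kernel: int):
        super().__init__()
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        return F.max_pool2d(x, self.kernel)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x
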