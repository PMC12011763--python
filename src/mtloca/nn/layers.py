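"""Layer/module abstractions on top of the functional ops."""
from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Parameter, Tensor

__all__ = ["Module", "Conv2d", "GroupNorm", "Linear", "Identity"]


class Module:
    """Base class; collects parameters recursively from attributes and lists."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def visit(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)

        visit(self)
        return params

    def named_parameters(self) -> dict[str, Parameter]:
        named: dict[str, Parameter] = {}

        def visit(obj, prefix):
            if isinstance(obj, Parameter):
                named[prefix] = obj
            elif isinstance(obj, Module):
                for k, v in vars(obj).items():
                    visit(v, f"{prefix}.{k}" if prefix else k)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    visit(v, f"{prefix}.{i}")

        visit(self, "")
        return named

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return int(np.sum([p.data.size for p in self.parameters()]))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        named = self.named_parameters()
        missing = set(named) - set(state)
        extra = set(state) - set(named)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)}, "
                             f"unexpected={sorted(extra)}")
        for k, p in named.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """3x3 or 1x1 'same' convolution with He-normal init."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, bias: bool = True,
                 dtype=np.float32):
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, std, size=(out_channels, in_channels,
                                       kernel_size, kernel_size))
        self.weight = Parameter(w.astype(dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias)


class GroupNorm(Module):
    def __init__(self, groups: int, channels: int, dtype=np.float32):
        if channels % groups:
            raise ValueError(f"channels {channels} not divisible by groups {groups}")
        self.groups = groups
        self.weight = Parameter(np.ones(channels, dtype=dtype))
        self.bias = Parameter(np.zeros(channels, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return F.group_norm(x, self.weight, self.bias, self.groups)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, dtype=np.float32):
        std = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, std, size=(in_features, out_features)).astype(dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return F.linear(x, self.weight, self.bias)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x
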