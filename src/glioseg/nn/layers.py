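"""Lightweight module/parameter containers for the segmentation networks."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor, as_tensor


def _walk(value, key):
    """Yield (name, parameter) pairs from modules/tensors nested in containers."""
    if isinstance(value, Tensor):
        if value.requires_grad:
            yield key, value
    elif isinstance(value, Module):
        yield from value.named_parameters(f"{key}.")
    elif isinstance(value, (list, tuple)):
        for i, item in enumerate(value):
            yield from _walk(item, f"{key}.{i}")


class Module:
    """Base class; parameters and child modules (however nested in
    lists/tuples) are discovered by attribute walk."""

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            yield from _walk(value, f"{prefix}{name}")

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, v in params.items():
            arr = np.asarray(state[k], dtype=v.data.dtype)
            if arr.shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {v.data.shape}")
            v.data = arr.copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape).astype(np.float32), requires_grad=True)


class Conv3d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1):
        if in_channels < 1 or out_channels < 1:
            raise ValueError("channel counts must be positive")
        self.weight = _he_init(rng, (out_channels, in_channels) + (kernel_size,) * 3,
                               fan_in=in_channels * kernel_size**3)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True)
        self.stride = stride

    def forward(self, x):
        return F.conv3d(x, self.weight, self.bias, stride=self.stride)


class ConvTranspose3d(Module):
    """Kernel-2, stride-2 transposed convolution (doubles each spatial axis)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        self.weight = _he_init(rng, (in_channels, out_channels, 2, 2, 2),
                               fan_in=in_channels * 8)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True)

    def forward(self, x):
        return F.conv_transpose3d_x2(x, self.weight, self.bias)


class InstanceNorm3d(Module):
    def __init__(self, channels: int, eps: float = 1e-5):
        self.weight = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def forward(self, x):
        return F.instance_norm(x, self.weight, self.bias, eps=self.eps)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.weight = _he_init(rng, (in_features, out_features), fan_in=in_features)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True)

    def forward(self, x):
        return as_tensor(x) @ self.weight + self.bias
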