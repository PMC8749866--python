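"""Layer objects over the autodiff tensor: 3D convolutions, group
normalization, and a tiny Module system with named parameters and
state-dict (de)serialization."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .conv import conv3d, conv_transpose3d


class Module:
    """Base class; parameters and submodules are discovered by attribute scan."""

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
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={missing}, extra={extra}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}"
                )
            p.data = np.asarray(state[name], dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv3d(Module):
    """kxkxk cross-correlation; He-normal init, zero bias."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        padding: int | None = None,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        if padding is None:
            padding = kernel_size // 2
        fan_in = in_channels * kernel_size**3
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, std, (out_channels, in_channels, *(kernel_size,) * 3)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose3d(Module):
    """Learned up-sampling; kernel size equals stride (default 2x)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        stride: int = 2,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * stride**3
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, std, (in_channels, out_channels, *(stride,) * 3)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose3d(x, self.weight, self.bias, self.stride)


class GroupNorm(Module):
    """Normalize over channel groups and all spatial positions."""

    def __init__(self, num_groups: int, num_channels: int, eps: float = 1e-5):
        if num_channels % num_groups:
            raise ValueError(
                f"num_groups={num_groups} must divide num_channels={num_channels}"
            )
        self.num_groups = num_groups
        self.num_channels = num_channels
        self.eps = eps
        self.gamma = Tensor(np.ones(num_channels), requires_grad=True)
        self.beta = Tensor(np.zeros(num_channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[:2]
        spatial = x.shape[2:]
        g = self.num_groups
        xg = x.reshape(n, g, -1)
        m = xg.mean(axis=2, keepdims=True)
        centred = xg - m
        var = (centred**2).mean(axis=2, keepdims=True)
        xn = centred / ((var + self.eps) ** 0.5)
        xn = xn.reshape(n, c, *spatial)
        shape = (1, c) + (1,) * len(spatial)
        return xn * self.gamma.reshape(shape) + self.beta.reshape(shape)
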