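"""Layer/module abstraction over the functional ops.

Mirrors the familiar Module API: parameter registration through
attribute assignment, ``parameters()`` / ``state_dict()`` traversal,
and a train/eval switch that batch normalization respects.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from . import functional as F
from .autograd import Parameter, Tensor


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, arr: np.ndarray):
        self._buffers[name] = arr
        object.__setattr__(self, name, arr)

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Parameter]]:
        for n, p in self._params.items():
            yield prefix + n, p
        for mn, m in self._modules.items():
            yield from m.named_parameters(prefix + mn + ".")

    def parameters(self) -> List[Parameter]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def named_buffers(self, prefix: str = "") -> Iterator[Tuple[str, np.ndarray]]:
        for n, b in self._buffers.items():
            yield prefix + n, b
        for mn, m in self._modules.items():
            yield from m.named_buffers(prefix + mn + ".")

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {n: p.data for n, p in self.named_parameters()}
        state.update({n: b for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for n, p in self.named_parameters():
            p.data = np.asarray(state[n], dtype=np.float32).reshape(p.shape)
        for n, b in self.named_buffers():
            b[...] = state[n]

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def forward(self, *args, **kwargs):
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self._seq = list(mods)
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)

    def __iter__(self):
        return iter(self._seq)

    def __getitem__(self, i):
        return self._seq[i]

    def forward(self, x):
        for m in self._seq:
            x = m(x)
        return x


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: List[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        setattr(self, f"m{len(self._list)}", m)
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


def _kaiming(shape, fan_in, rng: np.random.Generator) -> np.ndarray:
    bound = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, bound, size=shape).astype(np.float32)


_default_rng = np.random.default_rng(0)


def seed_init(seed: int) -> None:
    """Reseed weight initialization (used for deterministic model builds)."""
    global _default_rng
    _default_rng = np.random.default_rng(seed)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size,
        stride=1,
        padding=0,
        groups: int = 1,
        bias: bool = True,
    ):
        super().__init__()
        kh, kw = F._pair(kernel_size)
        if kh <= 0 or kw <= 0:
            raise ValueError("kernel size must be positive")
        sh, sw = F._pair(stride)
        if sh <= 0 or sw <= 0:
            raise ValueError("stride must be positive")
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.stride = (sh, sw)
        self.padding = F._pair(padding)
        self.groups = groups
        fan_in = in_channels // groups * kh * kw
        self.weight = Parameter(
            _kaiming((out_channels, in_channels // groups, kh, kw), fan_in, _default_rng)
        )
        self.bias = Parameter(np.zeros(out_channels, np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features, np.float32))
        self.bias = Parameter(np.zeros(num_features, np.float32))
        self.register_buffer("running_mean", np.zeros(num_features, np.float32))
        self.register_buffer("running_var", np.ones(num_features, np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm2d(
            x,
            self.weight,
            self.bias,
            self.running_mean,
            self.running_var,
            self.training,
            self.momentum,
            self.eps,
        )


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim, np.float32))
        self.bias = Parameter(np.zeros(dim, np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return F.layer_norm(x, self.weight, self.bias, self.eps)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_kaiming((out_features, in_features), in_features, _default_rng))
        self.bias = Parameter(np.zeros(out_features, np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.linear(x, self.weight, self.bias)


class SiLU(Module):
    def forward(self, x):
        return F.silu(x)


class Upsample(Module):
    """Bilinear upsampling by an integer scale factor."""

    def __init__(self, scale: int):
        super().__init__()
        self.scale = scale

    def forward(self, x):
        _, _, h, w = x.shape
        return F.interpolate_bilinear(x, (h * self.scale, w * self.scale))
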