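"""Layer/module abstractions over the autograd tensors.

Modules hold parameters as ``Tensor`` attributes and compose via attributes,
lists (:class:`ModuleList`) and :class:`Sequential`.  Parameter init draws
from a per-process RNG set with :func:`manual_seed`, so a single integer seed
makes model construction reproducible.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional, Sequence

import numpy as np

from oeyolo.nn import functional as F
from oeyolo.nn.tensor import Tensor

__all__ = [
    "manual_seed",
    "get_rng",
    "Module",
    "Sequential",
    "ModuleList",
    "Identity",
    "SiLU",
    "ReLU",
    "Sigmoid",
    "Conv2d",
    "Linear",
    "BatchNorm2d",
]

_RNG = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Seed parameter initialization globally."""
    global _RNG
    _RNG = np.random.default_rng(seed)


def get_rng() -> np.random.Generator:
    return _RNG


class Module:
    def __init__(self) -> None:
        self.training = True

    # -- containers --------------------------------------------------------
    def modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
        seen = set()
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad and id(v) not in seen:
                    seen.add(id(v))
                    params.append(v)
        return params

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- (de)serialization -------------------------------------------------
    def state_dict(self, prefix: str = "") -> Dict[str, np.ndarray]:
        state: Dict[str, np.ndarray] = {}
        self._collect_state(prefix, state)
        return state

    def _collect_state(self, prefix: str, state: Dict[str, np.ndarray]) -> None:
        for k, v in self.__dict__.items():
            if isinstance(v, Tensor):
                state[prefix + k] = v.data
            elif isinstance(v, np.ndarray):
                state[prefix + k] = v
            elif isinstance(v, Module):
                v._collect_state(prefix + k + ".", state)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item._collect_state(f"{prefix}{k}.{i}.", state)

    def load_state_dict(self, state: Dict[str, np.ndarray], prefix: str = "") -> None:
        for k, v in self.__dict__.items():
            if isinstance(v, Tensor):
                v.data = np.asarray(state[prefix + k], dtype=np.float32).reshape(v.data.shape)
            elif isinstance(v, np.ndarray):
                self.__dict__[k] = np.asarray(state[prefix + k], dtype=v.dtype).reshape(v.shape)
            elif isinstance(v, Module):
                v.load_state_dict(state, prefix + k + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_dict(state, f"{prefix}{k}.{i}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ModuleList(Module):
    def __init__(self, modules: Optional[Sequence[Module]] = None):
        super().__init__()
        self.items = list(modules or [])

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def __len__(self):
        return len(self.items)

    def append(self, m: Module) -> None:
        self.items.append(m)

    def forward(self, *a, **k):  # pragma: no cover
        raise NotImplementedError("ModuleList is a container")


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.silu()


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Conv2d(Module):
    """Dense or depthwise 2-D convolution with He-normal init."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: Optional[int] = None,
        groups: int = 1,
        bias: bool = True,
    ):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = kernel_size // 2 if padding is None else padding
        self.groups = groups
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Tensor(
            _RNG.normal(0.0, std, (out_channels, in_channels // groups, kernel_size, kernel_size)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        bound = float(np.sqrt(1.0 / in_features))
        self.weight = Tensor(
            _RNG.uniform(-bound, bound, (out_features, in_features)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight.transpose(1, 0)
        F.add_flops(2 * int(np.prod(x.shape[:-1])) * self.in_features * self.out_features)
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    """Batch normalization over NCHW with running statistics for eval."""

    def __init__(self, num_features: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Tensor(np.ones(num_features), requires_grad=True)
        self.bias = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        # fused forward/backward: this layer sits after every convolution,
        # so avoiding the composite-op graph here matters for throughput
        xd = x.data
        if self.training:
            mu = xd.mean(axis=(0, 2, 3), keepdims=True)
            var = ((xd - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (mu.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (var.reshape(-1) - self.running_var)
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            var = self.running_var.reshape(1, -1, 1, 1)
        inv_sigma = 1.0 / np.sqrt(var + self.eps)
        xhat = (xd - mu) * inv_sigma
        gamma = self.weight.data.reshape(1, -1, 1, 1)
        beta = self.bias.data.reshape(1, -1, 1, 1)
        out = Tensor(
            xhat * gamma + beta,
            requires_grad=x.requires_grad or self.weight.requires_grad,
            _prev=(x, self.weight, self.bias),
        )
        training = self.training

        def _bw(g):
            if self.weight.requires_grad:
                self.weight._acc((g * xhat).sum(axis=(0, 2, 3)))
            if self.bias.requires_grad:
                self.bias._acc(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gxhat = g * gamma
                if training:
                    m = xd.shape[0] * xd.shape[2] * xd.shape[3]
                    mean_g = gxhat.mean(axis=(0, 2, 3), keepdims=True)
                    mean_gx = (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
                    x._acc(inv_sigma * (gxhat - mean_g - xhat * mean_gx))
                else:
                    x._acc(inv_sigma * gxhat)

        out._backward = _bw
        return out
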