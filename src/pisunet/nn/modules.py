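"""Layer abstractions over the autograd core: Module, Conv2d, BatchNorm2d, ...

Weight initialisation is He-normal and every layer takes an explicit
``numpy.random.Generator`` so a model build is fully reproducible from a
single seed.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from . import functional as F
from .autograd import Tensor

__all__ = [
    "Module",
    "ModuleList",
    "Sequential",
    "Conv2d",
    "ConvTranspose2d",
    "Linear",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "Identity",
]


class Module:
    def __init__(self):
        self.training = True

    # ------------------------------------------------------------- traversal
    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield f"{prefix}{name}", value
        for name, child in self._children():
            yield from child.named_parameters(f"{prefix}{name}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    # ----------------------------------------------------------------- state
    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"__bnstat{i}.mean"] = m.running_mean.copy()
                state[f"__bnstat{i}.var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = state[name].astype(p.data.dtype, copy=True)
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean = state[f"__bnstat{i}.mean"].copy()
                m.running_var = state[f"__bnstat{i}.var"].copy()

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
        mods = list(mods)
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
        self._n = len(mods)

    def __len__(self):
        return self._n

    def __iter__(self):
        return (getattr(self, f"m{i}") for i in range(self._n))

    def __getitem__(self, i):
        return getattr(self, f"m{i}")

    def append(self, m: Module):
        setattr(self, f"m{self._n}", m)
        self._n += 1


class Sequential(ModuleList):
    def forward(self, x):
        for m in self:
            x = m(x)
        return x


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    """Stride-1 'same'-padded convolution."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        k = kernel_size
        self.weight = Tensor(_he(rng, (out_channels, in_channels, k, k), in_channels * k * k), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias)


class ConvTranspose2d(Module):
    """Kernel-2, stride-2 transposed convolution (learned 2x upsampling)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Tensor(_he(rng, (in_channels, out_channels, 2, 2), in_channels * 4), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return F.conv_transpose2x(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Tensor(_he(rng, (out_features, in_features), in_features), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return ag.linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.weight = Tensor(np.ones(num_features, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(num_features, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        return F.batch_norm2d(
            x, self.weight, self.bias, self.running_mean, self.running_var,
            self.training, self.momentum, self.eps,
        )


class ReLU(Module):
    def forward(self, x):
        return ag.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return ag.sigmoid(x)


class Identity(Module):
    def forward(self, x):
        return x
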