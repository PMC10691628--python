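"""Network building blocks: SE channel attention, Inception, pyramid pooling.

The squeeze-and-excitation (SE) gate compresses a feature map A of size
H x W per channel by global average pooling,

    z_k = (1 / (H·W)) Σ_i Σ_j A_k(i, j),

passes z through a two-layer bottleneck MLP,

    s = sigmoid(W2 · relu(W1 · z)),

and rescales each channel of the original map by its gate,
``out_k = s_k · A_k``.  The bottleneck width is ``max(1, C // r)`` with
reduction ratio r (default 16), so very narrow test models stay valid.

The Inception block runs four parallel branches — 1x1 conv; 1x1 then 3x3;
1x1 then 5x5; 3x3 max-pool then 1x1 — each producing ``out_channels/4``
channels at unchanged spatial size, concatenated along channels.  The 1x1
bottlenecks (width ``out_channels/8``) ahead of the large kernels are what
make the block cheaper than a single dense 3x3 convolution.

The pyramid pooling module (PPM) adaptively average-pools the map to p x p
grids (default p ∈ {1, 2, 4, 8}), reduces each pooled map with a 1x1 conv
to ``C / n_levels`` channels, bilinearly upsamples back to H x W,
concatenates everything with the input and fuses with a final 1x1 conv.
Output spatial size always equals input spatial size.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor
from .nn import functional as F
from .nn.autograd import relu as _relu
from .nn.autograd import reshape as _reshape
from .nn.autograd import sigmoid as _sigmoid

__all__ = [
    "se_squeeze",
    "se_excite",
    "se_scale",
    "SEBlock",
    "InceptionBlock",
    "PyramidPooling",
    "ConvBNReLU",
]


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def se_squeeze(a) -> Tensor:
    """Global average pool (N, C, H, W) -> per-channel statistics (N, C)."""
    return F.global_avg_pool(_as_tensor(a))


def se_excite(z, w1: nn.Linear, w2: nn.Linear) -> Tensor:
    """Two-layer gate: sigmoid(W2 relu(W1 z)); every output in (0, 1)."""
    z = _as_tensor(z)
    if z.ndim != 2:
        raise ValueError(f"expected (N, C) channel statistics, got shape {z.shape}")
    if w1.weight.shape[1] != z.shape[1]:
        raise ValueError(
            f"dimension mismatch: z has {z.shape[1]} channels, W1 expects {w1.weight.shape[1]}"
        )
    return _sigmoid(w2(_relu(w1(z))))


def se_scale(a, s) -> Tensor:
    """Channel-wise rescaling: out_k = s_k · A_k."""
    a = _as_tensor(a)
    s = _as_tensor(s)
    n, c = a.shape[0], a.shape[1]
    if s.shape != (n, c):
        raise ValueError(f"gate shape {s.shape} does not match feature map channels {(n, c)}")
    return a * _reshape(s, (n, c, 1, 1))


class SEBlock(nn.Module):
    """Squeeze -> excite -> scale, with bottleneck width max(1, C // r)."""

    def __init__(self, channels: int, rng: np.random.Generator, ratio: int = 16):
        super().__init__()
        hidden = max(1, channels // ratio)
        self.fc1 = nn.Linear(channels, hidden, rng)
        self.fc2 = nn.Linear(hidden, channels, rng)

    def forward(self, x):
        return se_scale(x, se_excite(se_squeeze(x), self.fc1, self.fc2))


class ConvBNReLU(nn.Module):
    def __init__(self, in_c: int, out_c: int, k: int, rng: np.random.Generator, batchnorm: bool = True):
        super().__init__()
        self.conv = nn.Conv2d(in_c, out_c, k, rng)
        self.bn = nn.BatchNorm2d(out_c) if batchnorm else nn.Identity()

    def forward(self, x):
        return _relu(self.bn(self.conv(x)))


class InceptionBlock(nn.Module):
    """Four-branch multi-scale convolution with 1x1 bottlenecks."""

    def __init__(self, in_c: int, out_c: int, rng: np.random.Generator, batchnorm: bool = True):
        super().__init__()
        if out_c % 4:
            raise ValueError(f"out_channels must be divisible by 4, got {out_c}")
        branch = out_c // 4
        neck = max(1, out_c // 8)
        self.b1 = ConvBNReLU(in_c, branch, 1, rng, batchnorm)
        self.b2 = nn.Sequential([
            ConvBNReLU(in_c, neck, 1, rng, batchnorm),
            ConvBNReLU(neck, branch, 3, rng, batchnorm),
        ])
        self.b3 = nn.Sequential([
            ConvBNReLU(in_c, neck, 1, rng, batchnorm),
            ConvBNReLU(neck, branch, 5, rng, batchnorm),
        ])
        self.b4_conv = ConvBNReLU(in_c, branch, 1, rng, batchnorm)

    def forward(self, x):
        x = _as_tensor(x)
        return nn.concat(
            [self.b1(x), self.b2(x), self.b3(x), self.b4_conv(F.max_pool_same3(x))],
            axis=1,
        )


class PyramidPooling(nn.Module):
    """Multi-scale context aggregation; preserves spatial size."""

    def __init__(
        self,
        in_c: int,
        out_c: int,
        rng: np.random.Generator,
        pool_sizes: tuple[int, ...] = (1, 2, 4, 8),
        batchnorm: bool = True,
    ):
        super().__init__()
        if not pool_sizes:
            raise ValueError("pool_sizes must be non-empty")
        self.pool_sizes = tuple(pool_sizes)
        reduced = max(1, in_c // len(self.pool_sizes))
        self.branches = nn.ModuleList(
            [ConvBNReLU(in_c, reduced, 1, rng, batchnorm) for _ in self.pool_sizes]
        )
        self.fuse = ConvBNReLU(in_c + reduced * len(self.pool_sizes), out_c, 1, rng, batchnorm)

    def forward(self, x):
        x = _as_tensor(x)
        h, w = x.shape[2], x.shape[3]
        feats = [x]
        for p, conv in zip(self.pool_sizes, self.branches):
            pooled = F.adaptive_avg_pool2d(x, p)
            feats.append(F.upsample_bilinear(conv(pooled), (h, w)))
        return self.fuse(nn.concat(feats, axis=1))
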