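"""The segmentation networks: U-Net backbone and its attention variants.

The backbone is a classic encoder–decoder U-Net: four downsampling levels,
each two stride-1 'same' 3x3 convolutions followed by 2x2 max pooling, with
channel width doubling per level; the decoder mirrors it with learned 2x2/
stride-2 transposed-convolution upsampling and skip-connection
concatenation; a final 1x1 convolution plus sigmoid yields a one-channel
probability map at input resolution.

Variants (the ablation matrix):

    ========== ==== ========== ====
    name        SE   Inception  PPM
    ========== ==== ========== ====
    unet         -       -       -
    se_unet      x       -       -
    ppm_unet     -       -       x
    is_unet      x       x       -
    pis_unet     x       x       x
    ========== ==== ========== ====

With Inception+SE enabled, the *second* 3x3 convolution of every block is
replaced by an Inception block followed by an SE gate; with SE alone, the
SE gate is appended after the second 3x3 convolution.  The pyramid pooling
module sits between the deepest encoder block and the first decoder
upsample.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .blocks import ConvBNReLU, InceptionBlock, PyramidPooling, SEBlock
from .nn import Tensor
from .nn.autograd import sigmoid as _sigmoid

__all__ = [
    "ModelConfig",
    "VARIANTS",
    "SegModel",
    "build_model",
    "count_parameters",
    "predict_mask",
    "save_checkpoint",
    "load_checkpoint",
]

# name -> (use_se, use_inception, use_ppm)
VARIANTS: dict[str, tuple[bool, bool, bool]] = {
    "unet": (False, False, False),
    "se_unet": (True, False, False),
    "ppm_unet": (False, False, True),
    "is_unet": (True, True, False),
    "pis_unet": (True, True, True),
}


@dataclass(frozen=True)
class ModelConfig:
    use_se: bool = False
    use_inception: bool = False
    use_ppm: bool = False
    base_channels: int = 64
    depth: int = 4
    ppm_pool_sizes: tuple[int, ...] = (1, 2, 4, 8)
    se_ratio: int = 16
    input_size: int = 512
    batchnorm: bool = True
    composite_in_bottleneck: bool = True
    upsample: str = "transposed"  # or "bilinear" (2x bilinear + 1x1 conv)

    @classmethod
    def for_variant(cls, name: str, **overrides) -> "ModelConfig":
        if name not in VARIANTS:
            raise ValueError(f"unknown variant {name!r}; choose from {sorted(VARIANTS)}")
        se, inc, ppm = VARIANTS[name]
        return cls(use_se=se, use_inception=inc, use_ppm=ppm, **overrides)

    def validate(self) -> None:
        if self.base_channels < 1 or self.depth < 1:
            raise ValueError("base_channels and depth must be >= 1")
        if self.input_size % (2**self.depth):
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 2^depth = {2**self.depth}"
            )
        if self.use_ppm and self.input_size % max(self.ppm_pool_sizes):
            raise ValueError("input_size must be divisible by max(ppm_pool_sizes)")
        if self.use_inception and (self.base_channels % 4):
            raise ValueError("base_channels must be divisible by 4 when using Inception blocks")
        if self.upsample not in ("transposed", "bilinear"):
            raise ValueError(f"unknown upsample mode {self.upsample!r}")

    def variant_name(self) -> str:
        key = (self.use_se, self.use_inception, self.use_ppm)
        for name, flags in VARIANTS.items():
            if flags == key:
                return name
        return "custom"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ppm_pool_sizes"] = list(self.ppm_pool_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "ppm_pool_sizes" in d:
            d["ppm_pool_sizes"] = tuple(d["ppm_pool_sizes"])
        return cls(**d)


class _BilinearUp(nn.Module):
    """2x bilinear upsampling followed by a 1x1 channel-mapping convolution."""

    def __init__(self, in_c: int, out_c: int, rng):
        super().__init__()
        self.conv = nn.Conv2d(in_c, out_c, 1, rng)

    def forward(self, x):
        h, w = x.shape[2], x.shape[3]
        return self.conv(nn.functional.upsample_bilinear(x, (2 * h, 2 * w)))


class _Block(nn.Module):
    """One U-Net level: first 3x3 conv, then either a second 3x3 conv, a
    conv+SE, or the Inception+SE composite, per the config flags."""

    def __init__(self, in_c: int, out_c: int, cfg: ModelConfig, rng, composite: bool):
        super().__init__()
        self.conv1 = ConvBNReLU(in_c, out_c, 3, rng, cfg.batchnorm)
        use_inc = cfg.use_inception and composite
        if use_inc:
            self.second = InceptionBlock(out_c, out_c, rng, cfg.batchnorm)
        else:
            self.second = ConvBNReLU(out_c, out_c, 3, rng, cfg.batchnorm)
        self.se = SEBlock(out_c, rng, cfg.se_ratio) if cfg.use_se else nn.Identity()

    def forward(self, x):
        return self.se(self.second(self.conv1(x)))


class SegModel(nn.Module):
    """Binary lesion segmenter; input (N, 1, H, W), output (N, 1, H, W) in (0, 1)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.base_channels
        enc_channels = [c * 2**i for i in range(config.depth)]
        bott_c = c * 2**config.depth

        self.encoders = nn.ModuleList(
            [
                _Block(1 if i == 0 else enc_channels[i - 1], enc_channels[i], config, rng, composite=True)
                for i in range(config.depth)
            ]
        )
        self.bottleneck = _Block(
            enc_channels[-1], bott_c, config, rng, composite=config.composite_in_bottleneck
        )
        self.ppm = (
            PyramidPooling(bott_c, bott_c, rng, config.ppm_pool_sizes, config.batchnorm)
            if config.use_ppm
            else nn.Identity()
        )
        ups, decs = [], []
        ch = bott_c
        for i in reversed(range(config.depth)):
            if config.upsample == "transposed":
                ups.append(nn.ConvTranspose2d(ch, enc_channels[i], rng))
            else:
                ups.append(_BilinearUp(ch, enc_channels[i], rng))
            decs.append(_Block(2 * enc_channels[i], enc_channels[i], config, rng, composite=True))
            ch = enc_channels[i]
        self.ups = nn.ModuleList(ups)
        self.decoders = nn.ModuleList(decs)
        self.head = nn.Conv2d(enc_channels[0], 1, 1, rng)

    def forward(self, x):
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        skips = []
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
            x = nn.functional.max_pool2d(x)
        x = self.ppm(self.bottleneck(x))
        for up, dec, skip in zip(self.ups, self.decoders, reversed(skips)):
            x = dec(nn.concat([skip, up(x)], axis=1))
        return _sigmoid(self.head(x))


def build_model(config: ModelConfig, seed: int = 0) -> SegModel:
    """Construct a (deterministically initialised) segmentation network."""
    return SegModel(config, seed)


def count_parameters(model: nn.Module) -> int:
    """Total number of trainable scalar parameters."""
    return sum(p.size for p in model.parameters() if p.requires_grad)


def predict_mask(model: SegModel, image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Run one preprocessed 2-D image through the model and binarise.

    Returns a uint8 {0, 1} mask of the same spatial size as the input.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    size = model.config.input_size
    if image.shape != (size, size):
        raise ValueError(f"image shape {image.shape} does not match model input {(size, size)}")
    was_training = model.training
    model.eval()
    prob = model(image[None, None]).data[0, 0]
    if was_training:
        model.train()
    return (prob > threshold).astype(np.uint8)


def save_checkpoint(model: SegModel, path: Path | str) -> None:
    """Framework-native weights (.npz) plus a sidecar JSON with the config."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    np.savez(path, **model.state_dict())
    path.with_suffix(".json").write_text(json.dumps(model.config.to_dict(), indent=2))


def load_checkpoint(path: Path | str, seed: int = 0) -> SegModel:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    config = ModelConfig.from_dict(json.loads(path.with_suffix(".json").read_text()))
    model = SegModel(config, seed)
    with np.load(path) as data:
        model.load_state_dict(dict(data))
    return model
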