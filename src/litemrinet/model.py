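"""The LiteMRINet architecture.

The network encodes a three-level image pyramid (full, half and quarter
resolution) with a *single* 10-layer convolutional stack whose weights are
shared across the scales — the scale-invariance hypothesis: the same
kernels should recognize tumor tissue regardless of apparent size.  The
quarter-scale features then pass through two Transformer stages (6 and 4
pre-norm blocks, 8 attention heads) at the two smallest grids to capture
global context, and a UNet-style decoder upsamples back to full
resolution, fusing each encoder/bottleneck map by concatenation.  A final
1x1 convolution produces 2-channel (background/tumor) logits.

Three ablation variants are supported:

``transformer_sharecnn``
    the full model (one shared encoder weight store);
``transformer_cnn``
    identical except each scale has its own independent encoder copy;
``cnn_only``
    additionally replaces the two Transformer stages with equal-depth
    stacks of 3x3 conv layers, so depth is controlled.
"""

from __future__ import annotations

import dataclasses
import json
from typing import NamedTuple

import numpy as np
import yaml

from . import nn

__all__ = [
    "VARIANTS",
    "ModelConfig",
    "ScalePyramid",
    "DimensionError",
    "ConfigurationError",
    "build_pyramid",
    "LiteMRINet",
    "model_forward",
    "count_trainable_parameters",
    "build_variant",
    "save_checkpoint",
    "load_checkpoint",
]

VARIANTS = ("cnn_only", "transformer_cnn", "transformer_sharecnn")


class DimensionError(ValueError):
    """An input or feature map has an incompatible shape."""


class ConfigurationError(ValueError):
    """A model configuration is invalid or inconsistent."""


@dataclasses.dataclass
class ModelConfig:
    """Architectural hyperparameters.

    Defaults reproduce the published configuration: 256x256x3 input,
    a shared 10-layer 64-channel encoder, 6- and 4-block Transformer
    stages with 8 heads, and a 2-class head.
    """

    input_size: int = 256
    in_channels: int = 3
    base_channels: int = 64
    shared_depth: int = 10
    conv_kernel: int = 3
    transformer_depths: tuple[int, int] = (6, 4)
    attention_heads: int = 8
    ffn_expansion: int = 4
    use_positional_embedding: bool = True
    num_classes: int = 2
    variant: str = "transformer_sharecnn"

    def __post_init__(self):
        if self.input_size % 16:
            raise ConfigurationError(
                f"input_size must be divisible by 16, got {self.input_size}")
        if self.base_channels % self.attention_heads:
            raise ConfigurationError(
                f"attention_heads ({self.attention_heads}) must divide "
                f"base_channels ({self.base_channels})")
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown variant {self.variant!r}; valid: {', '.join(VARIANTS)}")
        if self.conv_kernel % 2 == 0:
            raise ConfigurationError("conv_kernel must be odd")
        self.transformer_depths = tuple(self.transformer_depths)

    @property
    def token_grids(self) -> tuple[int, int]:
        """Side lengths of the two bottleneck token lattices (S/8, S/16)."""
        return (self.input_size // 8, self.input_size // 16)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["transformer_depths"] = list(self.transformer_depths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "ModelConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_file(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


class ScalePyramid(NamedTuple):
    """The input image at full, half and quarter side length."""

    level_0: np.ndarray
    level_1: np.ndarray
    level_2: np.ndarray


def _half(x: np.ndarray) -> np.ndarray:
    """Area-average (antialiased) x1/2 downsampling of (..., H, W, C)."""
    h, w = x.shape[-3], x.shape[-2]
    s = x.reshape(*x.shape[:-3], h // 2, 2, w // 2, 2, x.shape[-1])
    return s.mean(axis=(-2, -4))


def build_pyramid(image: np.ndarray, input_size: int | None = None) -> ScalePyramid:
    """Downsample an image (or batch) to the three encoder scales.

    Accepts ``(H, W, C)`` or ``(N, H, W, C)``; the full-resolution level
    is the input unchanged, the other two are area-averaged x1/2 steps.
    """
    image = np.asarray(image)
    if image.ndim not in (3, 4):
        raise DimensionError(f"expected (H, W, C) or (N, H, W, C), got shape {image.shape}")
    h, w = image.shape[-3], image.shape[-2]
    if h != w:
        raise DimensionError(f"input must be square, got {h}x{w}")
    if h % 4:
        raise DimensionError(f"input side must be divisible by 4, got {h}")
    if input_size is not None and h != input_size:
        raise DimensionError(f"input side {h} does not match configured size {input_size}")
    level_1 = _half(image)
    level_2 = _half(level_1)
    return ScalePyramid(image, level_1, level_2)


class _Encoder(nn.Module):
    """A stack of shared_depth ConvBNReLU layers (one weight store).

    ``stats_groups`` gives each pyramid level its own batch-norm running
    statistics while every trainable parameter stays shared; ``scale``
    at forward time selects the statistics stream.
    """

    def __init__(self, cfg: ModelConfig, rng, stats_groups: int = 1):
        super().__init__()
        layers = [nn.ConvBNReLU(cfg.in_channels, cfg.base_channels, cfg.conv_kernel,
                                rng=rng, stats_groups=stats_groups)]
        for _ in range(cfg.shared_depth - 1):
            layers.append(nn.ConvBNReLU(cfg.base_channels, cfg.base_channels,
                                        cfg.conv_kernel, rng=rng,
                                        stats_groups=stats_groups))
        self.layers = nn.ModuleList(layers)

    def forward(self, x, scale: int = 0):
        for layer in self.layers:
            x = layer(x, group=scale)
        return x


class _TransformerStage(nn.Module):
    """Max-pool x2 then a stack of Transformer blocks on pixel tokens."""

    def __init__(self, cfg: ModelConfig, depth: int, token_grid: int, rng):
        super().__init__()
        self.pool = nn.MaxPool2x2()
        self.pos = (nn.PositionalEmbedding(token_grid**2, cfg.base_channels, rng=rng)
                    if cfg.use_positional_embedding else None)
        self.blocks = nn.Sequential([
            nn.TransformerBlock(cfg.base_channels, cfg.attention_heads,
                                cfg.ffn_expansion, rng=rng)
            for _ in range(depth)
        ])
        self.token_grid = token_grid

    def forward(self, x):
        if x.shape[1] % 2 or x.shape[2] % 2:
            raise DimensionError(f"transformer stage needs even spatial side, got {x.shape}")
        x = self.pool(x)
        n, h, w, c = x.shape
        tokens = x.reshape(n, h * w, c)
        if self.pos is not None:
            if h != self.token_grid:
                raise DimensionError(
                    f"token grid {h} does not match positional embedding "
                    f"grid {self.token_grid}")
            tokens = self.pos(tokens)
        tokens = self.blocks(tokens)
        return tokens.reshape(n, h, w, c)


class _ConvStage(nn.Module):
    """Ablation stand-in for a Transformer stage: pool then conv layers."""

    def __init__(self, cfg: ModelConfig, depth: int, rng):
        super().__init__()
        self.pool = nn.MaxPool2x2()
        self.layers = nn.Sequential([
            nn.ConvBNReLU(cfg.base_channels, cfg.base_channels, cfg.conv_kernel, rng=rng)
            for _ in range(depth)
        ])

    def forward(self, x):
        if x.shape[1] % 2 or x.shape[2] % 2:
            raise DimensionError(f"conv stage needs even spatial side, got {x.shape}")
        return self.layers(self.pool(x))


class _DecoderStage(nn.Module):
    """Upsample x2, one conv layer, fuse the skip, two conv layers."""

    def __init__(self, cfg: ModelConfig, name: str, rng):
        super().__init__()
        c = cfg.base_channels
        self.up = nn.BilinearUpsample2x()
        self.conv_up = nn.ConvBNReLU(c, c, cfg.conv_kernel, rng=rng)
        self.fuse1 = nn.ConvBNReLU(2 * c, c, cfg.conv_kernel, rng=rng)
        self.fuse2 = nn.ConvBNReLU(c, c, cfg.conv_kernel, rng=rng)
        self.name = name

    def forward(self, x, skip):
        x = self.conv_up(self.up(x))
        if x.shape != skip.shape:
            raise DimensionError(
                f"decoder stage {self.name}: upsampled map {x.shape} does not "
                f"match skip {skip.shape}")
        return self.fuse2(self.fuse1(nn.concat([x, skip], axis=-1)))


class _Decoder(nn.Module):
    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        self.stages = nn.ModuleList([
            _DecoderStage(cfg, name, rng)
            for name in ("s16->s8", "s8->s4", "s4->s2", "s2->s1")
        ])
        self.head = nn.Conv2d(cfg.base_channels, cfg.num_classes, kernel_size=1, rng=rng)

    def forward(self, skips, bottom):
        x = bottom
        for stage, skip in zip(self.stages, reversed(skips)):
            x = stage(x, skip)
        return self.head(x)


class LiteMRINet(nn.Module):
    """The full segmentation network (all three variants).

    Parameters
    ----------
    config
        Architectural hyperparameters; ``config.variant`` selects the
        full model or one of the ablations.
    seed
        Seed for weight initialization.
    """

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        super().__init__()
        cfg = config or ModelConfig()
        rng = np.random.default_rng(seed)
        self.config = cfg

        if cfg.variant == "transformer_sharecnn":
            self.encoder = _Encoder(cfg, rng, stats_groups=3)
            self._encoders = None
        else:
            self._encoders = nn.ModuleList([_Encoder(cfg, rng) for _ in range(3)])
            self.encoder = None

        g1, g2 = cfg.token_grids
        d1, d2 = cfg.transformer_depths
        if cfg.variant == "cnn_only":
            self.stage1 = _ConvStage(cfg, d1, rng)
            self.stage2 = _ConvStage(cfg, d2, rng)
        else:
            self.stage1 = _TransformerStage(cfg, d1, g1, rng)
            self.stage2 = _TransformerStage(cfg, d2, g2, rng)

        self.decoder = _Decoder(cfg, rng)

    # ------------------------------------------------------------------
    def encode(self, pyramid: ScalePyramid) -> list[nn.Tensor]:
        """Run the (shared or per-scale) encoder over the three levels."""
        levels = [nn.Tensor(np.asarray(lv, dtype=np.float32)) for lv in pyramid]
        for lv in levels:
            if lv.shape[-1] != self.config.in_channels:
                raise ConfigurationError(
                    f"pyramid has {lv.shape[-1]} channels, encoder expects "
                    f"{self.config.in_channels}")
        if self.encoder is not None:
            return [self.encoder(lv, scale=i) for i, lv in enumerate(levels)]
        return [enc(lv) for enc, lv in zip(self._encoders, levels)]

    def forward(self, images: np.ndarray) -> nn.Tensor:
        """Map ``(N, S, S, 3)`` images (values in [0, 1]) to ``(N, S, S, K)`` logits."""
        images = np.asarray(images, dtype=np.float32)
        squeeze = images.ndim == 3
        if squeeze:
            images = images[None]
        pyramid = build_pyramid(images, self.config.input_size)
        f0, f1, f2 = self.encode(pyramid)
        t1 = self.stage1(f2)        # S/8 grid
        t2 = self.stage2(t1)        # S/16 grid
        logits = self.decoder([f0, f1, f2, t1], t2)
        return logits[0] if squeeze else logits

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Inference: argmax over the class channel, returns a binary mask."""
        was_training = self.training
        self.eval()
        try:
            with nn.autograd.no_grad():
                logits = self.forward(images).data
        finally:
            self.train(was_training)
        return np.argmax(logits, axis=-1).astype(np.uint8)

    def shared_encoder_parameter_count(self) -> int:
        """Trainable scalars in one encoder weight store."""
        enc = self.encoder if self.encoder is not None else self._encoders[0]
        return enc.num_parameters()


def model_forward(image: np.ndarray, config: ModelConfig | None = None,
                  seed: int = 0) -> np.ndarray:
    """Convenience: build a freshly initialized model and run inference."""
    model = LiteMRINet(config, seed=seed).eval()
    return model.forward(image).data


def count_trainable_parameters(config: ModelConfig | None = None) -> int:
    """Total number of trainable scalar parameters for a configuration."""
    return LiteMRINet(config or ModelConfig(), seed=0).num_parameters()


def build_variant(name: str) -> ModelConfig:
    """Default configuration for one of the ablation variants."""
    if name not in VARIANTS:
        raise ConfigurationError(
            f"unknown variant {name!r}; valid names: {', '.join(VARIANTS)}")
    return ModelConfig(variant=name)


def save_checkpoint(model: LiteMRINet, path) -> str:
    """Serialize weights plus an embedded config snapshot (self-describing)."""
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    state = model.state_dict()
    np.savez(path, __config__=np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8), **state)
    return path


def load_checkpoint(path) -> LiteMRINet:
    with np.load(path) as data:
        cfg = ModelConfig.from_dict(json.loads(bytes(data["__config__"]).decode()))
        model = LiteMRINet(cfg, seed=0)
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
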