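"""Assembly of the full classifier and its ablation variants.

The full model (variant F) is a two-scale backbone:

* shallow path — three VGG-style spatial blocks (3x3 conv, batch norm,
  ReLU), the first with 2x2 max pooling and the second with 2x2 average
  pooling, both stride 2;
* deep path — four residual blocks with strided convolutions (strides
  1, 2, 2, 2) doing the remaining downsampling;
* two strip-pooling combination heads tapping the output of the third
  spatial block and the fourth residual block.  The heads are side
  branches: the backbone feeds the raw spatial-block-3 output into the
  first residual block.  Each head emits a length-D vector; the two are
  concatenated (2D features) and a single linear layer plus softmax gives
  the 4-class probabilities.

Ablation variants reuse the same pieces:

===  =========================================================
A    spatial blocks only, plain head (global avg pool + FC)
B    spatial blocks + shallow strip-pooling combination head
C    residual blocks only, plain head
D    residual blocks + deep strip-pooling combination head
E    full backbone, two plain heads, concatenated
F    full model (both strip-pooling combination heads)
===  =========================================================

Default widths — spatial (32, 64, 128), residual (128, 256, 384, 512),
head dimension 256 — put variant F at ~10.1 M trainable parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import Tensor, concat, softmax
from .nn import (
    Linear,
    Module,
    ResidualBlock,
    ResidualBlockConfig,
    SpatialBlock,
    SpatialBlockConfig,
)
from .strip import ComboHead, PlainHead

__all__ = ["ModelConfig", "StripFusionNet", "build_model", "build_variant", "VARIANTS"]

VARIANTS = ("A", "B", "C", "D", "E", "F")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; defaults are the full-scale model."""

    input_channels: int = 1
    num_classes: int = 4
    spatial_widths: tuple[int, int, int] = (32, 64, 128)
    residual_widths: tuple[int, int, int, int] = (128, 256, 384, 512)
    residual_strides: tuple[int, int, int, int] = (1, 2, 2, 2)
    head_dim: int = 256
    dropout_rate: float = 0.3
    variant: str = "F"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if len(self.spatial_widths) != 3 or len(self.residual_widths) != 4:
            raise ValueError("expected 3 spatial widths and 4 residual widths")

    def scaled(self, factor: int) -> "ModelConfig":
        """A width-divided copy (e.g. ``factor=4`` for the reduced test model)."""
        d = asdict(self)
        d["spatial_widths"] = tuple(max(1, w // factor) for w in self.spatial_widths)
        d["residual_widths"] = tuple(max(1, w // factor) for w in self.residual_widths)
        d["head_dim"] = max(1, self.head_dim // factor)
        return ModelConfig(**d)


class StripFusionNet(Module):
    """The classifier network for any of the variants A-F."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        v = cfg.variant
        self.has_spatial = v in ("A", "B", "E", "F")
        self.has_residual = v in ("C", "D", "E", "F")
        self.shallow_strip = v in ("B", "F")
        self.deep_strip = v in ("D", "F")

        sw = cfg.spatial_widths
        rw = cfg.residual_widths
        rs = cfg.residual_strides
        pools = ("max", "avg", None)
        if self.has_spatial:
            chans = (cfg.input_channels,) + sw
            self.spatial_blocks = [
                SpatialBlock(SpatialBlockConfig(chans[i], chans[i + 1], pools[i]), rng=rng)
                for i in range(3)
            ]
        if self.has_residual:
            res_in = sw[-1] if self.has_spatial else cfg.input_channels
            chans = (res_in,) + rw
            self.residual_blocks = [
                ResidualBlock(ResidualBlockConfig(chans[i], chans[i + 1], rs[i]), rng=rng)
                for i in range(4)
            ]

        def head(channels: int, strip: bool) -> Module:
            if strip:
                return ComboHead(channels, cfg.head_dim, cfg.dropout_rate, rng=rng)
            return PlainHead(channels, cfg.head_dim, rng=rng)

        feature_dim = 0
        if v in ("A", "B"):
            self.shallow_head = head(sw[-1], self.shallow_strip)
            feature_dim = cfg.head_dim
        elif v in ("C", "D"):
            self.deep_head = head(rw[-1], self.deep_strip)
            feature_dim = cfg.head_dim
        else:  # E, F: both taps, concatenated
            self.shallow_head = head(sw[-1], self.shallow_strip)
            self.deep_head = head(rw[-1], self.deep_strip)
            feature_dim = 2 * cfg.head_dim
        self.classifier = Linear(feature_dim, cfg.num_classes, rng=rng)

    # -- forward --------------------------------------------------------------

    def forward_logits(self, x: Tensor) -> Tensor:
        if x.data.ndim != 4 or x.data.shape[1] != self.cfg.input_channels:
            raise ValueError(
                "expected input of shape (B, "
                f"{self.cfg.input_channels}, H, W); got {x.data.shape}"
            )
        features = []
        out = x
        if self.has_spatial:
            for block in self.spatial_blocks:
                out = block(out)
            if hasattr(self, "shallow_head"):
                features.append(self.shallow_head(out))
        if self.has_residual:
            for block in self.residual_blocks:
                out = block(out)
            if hasattr(self, "deep_head"):
                features.append(self.deep_head(out))
        fused = features[0] if len(features) == 1 else concat(features, axis=1)
        return self.classifier(fused)

    def forward(self, x: Tensor | np.ndarray) -> np.ndarray:
        """Class probabilities (rows sum to 1) for a batch, without gradients."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        return softmax(self.forward_logits(x).data)

    predict_proba = forward

    def predict(self, x: Tensor | np.ndarray) -> np.ndarray:
        return self.forward(x).argmax(axis=1)

    # -- reporting ------------------------------------------------------------

    def combo_head_count(self) -> int:
        return sum(1 for m in self.modules() if isinstance(m, ComboHead))

    def summary(self) -> str:
        lines = [f"StripFusionNet variant {self.cfg.variant}"]
        groups: dict[str, int] = {}
        for name, p in self.named_parameters():
            top = name.split(".")[0]
            groups[top] = groups.get(top, 0) + p.data.size
        for top, count in groups.items():
            lines.append(f"  {top:<18s} {count:>12,d} params")
        lines.append(f"  {'total':<18s} {self.num_parameters():>12,d} params")
        return "\n".join(lines)


def build_model(cfg: ModelConfig, seed: int | None = None) -> StripFusionNet:
    """Construct a network from a config with reproducible initialisation."""
    rng = np.random.default_rng(seed)
    return StripFusionNet(cfg, rng=rng)


def build_variant(name: str, seed: int | None = None, **overrides) -> StripFusionNet:
    """Construct one of the ablation variants A-F with default widths."""
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; choose from {VARIANTS}")
    cfg = ModelConfig(variant=name, **overrides)
    return build_model(cfg, seed=seed)
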