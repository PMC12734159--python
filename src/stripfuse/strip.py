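"""Strip pooling: directional pooling, the attention gate, and the combo head.

Square pooling windows average anisotropic structures (elongated, irregular
lesions) together with their background.  Strip pooling instead aggregates a
feature map along entire rows and entire columns, producing one descriptor
per row and one per column.  The attention module turns those descriptors
into a multiplicative gate:

    rows  = mean over width   -> 1-D conv (k=3, channel-mixing) -> batch norm
    cols  = mean over height  -> 1-D conv (k=3, channel-mixing) -> batch norm
    fused = broadcast(rows) + broadcast(cols)          (H x W again)
    gate  = sigmoid(1x1 conv(fused))                   elementwise in (0, 1)
    out   = Z * gate

The combination head used at the two tap points of the full model is
strip-attention -> global average pooling -> dropout -> fully connected
layer, yielding a fixed-length feature vector per batch item.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .nn import BatchNorm1d, Conv1d, Conv2d, Dropout, Linear, Module

__all__ = [
    "strip_pool_horizontal",
    "strip_pool_vertical",
    "StripAttention",
    "ComboHead",
    "PlainHead",
]


def _rows(z: Tensor) -> Tensor:
    """Per-row means: (B, C, H, W) -> (B, C, H)."""
    return z.mean(axis=3)


def _cols(z: Tensor) -> Tensor:
    """Per-column means: (B, C, H, W) -> (B, C, W)."""
    return z.mean(axis=2)


def strip_pool_horizontal(z: np.ndarray) -> np.ndarray:
    """Horizontal strip pooling of an NCHW array: mean across the width."""
    z = np.asarray(z)
    if z.ndim != 4:
        raise ValueError("expected a rank-4 (B, C, H, W) array")
    return z.mean(axis=3)


def strip_pool_vertical(z: np.ndarray) -> np.ndarray:
    """Vertical strip pooling of an NCHW array: mean across the height."""
    z = np.asarray(z)
    if z.ndim != 4:
        raise ValueError("expected a rank-4 (B, C, H, W) array")
    return z.mean(axis=2)


class StripAttention(Module):
    """Directional strip-pooling attention gate; output shape equals input."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.channels = channels
        self.conv_h = Conv1d(channels, channels, 3, rng=rng)
        self.conv_v = Conv1d(channels, channels, 3, rng=rng)
        self.bn_h = BatchNorm1d(channels)
        self.bn_v = BatchNorm1d(channels)
        self.conv_fuse = Conv2d(channels, channels, 1, padding=0, rng=rng)

    def forward(self, z: Tensor) -> Tensor:
        b, c, h, w = z.data.shape
        if h < 3 or w < 3:
            raise ValueError("strip attention needs spatial dimensions >= 3")
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        rows = self.bn_h(self.conv_h(_rows(z)))  # (B, C, H)
        cols = self.bn_v(self.conv_v(_cols(z)))  # (B, C, W)
        # broadcast-expand each direction back to H x W and fuse by summation
        fused = rows.reshape(b, c, h, 1) + cols.reshape(b, c, 1, w)
        gate = self.conv_fuse(fused).sigmoid()
        return z * gate

    def gate(self, z: Tensor) -> Tensor:
        """The attention weights alone (each element strictly inside (0, 1))."""
        b, c, h, w = z.data.shape
        rows = self.bn_h(self.conv_h(_rows(z)))
        cols = self.bn_v(self.conv_v(_cols(z)))
        fused = rows.reshape(b, c, h, 1) + cols.reshape(b, c, 1, w)
        return self.conv_fuse(fused).sigmoid()


class ComboHead(Module):
    """Strip attention -> global average pool -> dropout -> fully connected.

    Produces a length-``out_dim`` feature vector per batch item.  Dropout is
    active only in training mode, so evaluation is deterministic.
    """

    def __init__(
        self,
        channels: int,
        out_dim: int,
        dropout_rate: float = 0.3,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        self.attention = StripAttention(channels, rng=rng)
        self.dropout = Dropout(dropout_rate, rng=rng)
        self.fc = Linear(channels, out_dim, rng=rng)

    def forward(self, z: Tensor) -> Tensor:
        attended = self.attention(z)
        pooled = attended.mean(axis=(2, 3))  # (B, C)
        return self.fc(self.dropout(pooled))


class PlainHead(Module):
    """Ablation head: global average pool -> fully connected, nothing else."""

    def __init__(self, channels: int, out_dim: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.fc = Linear(channels, out_dim, rng=rng)

    def forward(self, z: Tensor) -> Tensor:
        return self.fc(z.mean(axis=(2, 3)))
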