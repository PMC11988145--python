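"""DenseNet backbone with Squeeze-and-Excitation gating and a binary head.

The fused feature vector is reshaped (bijectively) into a small C×h×w
feature map, passed through a stem convolution and three dense blocks.
Inside a dense block every layer consumes the concatenation of the block
input and all previous layer outputs, so a block with L layers and growth
rate g adds L·g channels. After each dense block an SE block re-weights
channels: global average pool -> bottleneck FC (reduce by r) -> ReLU ->
restore FC -> sigmoid gate in (0,1) multiplied back onto the channels.
Average pooling (stride 2) downsamples between blocks; a global average
pool and a fully connected layer produce the two class logits
(estrus vs non-estrus).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor


@dataclass(frozen=True)
class DenseNetSEConfig:
    reshape: tuple[int, int, int] = (4, 8, 8)   # fused vector -> (C0, h0, w0)
    stem_channels: int = 16
    block_layers: tuple[int, int, int] = (4, 4, 4)
    growth_rate: int = 12
    se_reduction: int = 16
    num_classes: int = 2
    use_se: bool = True

    @property
    def fused_dim(self) -> int:
        c, h, w = self.reshape
        return c * h * w

    def channel_schedule(self) -> list[int]:
        """Channel count entering/leaving each dense block (audit hook)."""
        chans = [self.stem_channels]
        for layers in self.block_layers:
            chans.append(chans[-1] + layers * self.growth_rate)
        return chans


def reshape_fused(fused: np.ndarray, cfg: DenseNetSEConfig) -> np.ndarray:
    """Bijective (..., C0·h0·w0) -> (..., C0, h0, w0) reshape."""
    c, h, w = cfg.reshape
    if fused.shape[-1] != c * h * w:
        raise ValueError(
            f"fused dim {fused.shape[-1]} != reshape target {c}x{h}x{w}")
    return fused.reshape(*fused.shape[:-1], c, h, w)


def unreshape_fused(fmap: np.ndarray, cfg: DenseNetSEConfig) -> np.ndarray:
    c, h, w = cfg.reshape
    return fmap.reshape(*fmap.shape[:-3], c * h * w)


class SEBlock(nn.Module):
    """Squeeze-and-Excitation channel gate."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        mid = max(1, channels // reduction)
        self.fc1 = nn.Linear(channels, mid, rng)
        self.fc2 = nn.Linear(mid, channels, rng)

    def gate(self, x: Tensor) -> Tensor:
        squeezed = x.mean(axis=3).mean(axis=2)           # (B, C) GAP
        return nn.sigmoid(self.fc2(nn.relu(self.fc1(squeezed))))

    def __call__(self, x: Tensor) -> Tensor:
        s = self.gate(x)
        B, C = s.shape
        return x * s.reshape(B, C, 1, 1)


class DenseBlock(nn.Module):
    """L conv layers, each fed the concatenation of all previous outputs."""

    def __init__(self, in_channels: int, layers: int, growth: int,
                 rng: np.random.Generator):
        self.convs = [
            nn.Conv2d(in_channels + i * growth, growth, 3, rng)
            for i in range(layers)
        ]
        self.out_channels = in_channels + layers * growth

    def __call__(self, x: Tensor) -> Tensor:
        feats = x
        for conv in self.convs:
            new = conv(nn.relu(feats))
            feats = nn.concat([feats, new], axis=1)
        return feats


class DenseNetSE(nn.Module):
    """Stem conv -> [dense block -> SE -> avg pool]×3 -> GAP -> FC head."""

    def __init__(self, cfg: DenseNetSEConfig, rng: np.random.Generator):
        self.cfg = cfg
        c0 = cfg.reshape[0]
        self.stem = nn.Conv2d(c0, cfg.stem_channels, 3, rng)
        chans = cfg.channel_schedule()
        self.blocks = [
            DenseBlock(chans[i], cfg.block_layers[i], cfg.growth_rate, rng)
            for i in range(3)
        ]
        self.se_blocks = [
            SEBlock(chans[i + 1], cfg.se_reduction, rng) for i in range(3)
        ]
        self.head = nn.Linear(chans[-1], cfg.num_classes, rng)

    def __call__(self, fused: Tensor) -> Tensor:
        """(B, fused_dim) -> (B, num_classes) logits."""
        c, h, w = self.cfg.reshape
        B = fused.shape[0]
        x = fused.reshape(B, c, h, w)
        x = self.stem(x)
        for block, se in zip(self.blocks, self.se_blocks):
            x = block(x)
            if self.cfg.use_se:
                x = se(x)
            if x.shape[2] >= 2 and x.shape[3] >= 2:
                x = nn.avg_pool2d(x, 2)
        x = x.mean(axis=3).mean(axis=2)   # global average pool
        return self.head(x)

    def force_se_identity(self, bias: float = 1e4) -> None:
        """Saturate every SE gate at exactly 1 (sigmoid underflow), turning
        DenseNet-SE into plain DenseNet bit-for-bit — ablation wiring hook."""
        for se in self.se_blocks:
            se.fc1.W.data[:] = 0.0
            se.fc1.b.data[:] = 0.0
            se.fc2.W.data[:] = 0.0
            se.fc2.b.data[:] = bias


def classify(fused: np.ndarray, model: DenseNetSE) -> np.ndarray:
    """Single fused vector -> 2 logits; argmax is the predicted class."""
    return model(Tensor(fused[None, :])).data[0].copy()
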