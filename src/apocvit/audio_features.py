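"""Three-layer CNN audio feature extractor with a dilated third layer.

The denoised waveform runs through three convolution/ReLU/average-pool
stages; the third convolution is dilated, which widens its receptive field
without adding parameters (gaps between kernel taps carry no weights).
Global average pooling over time followed by a linear map yields the
fixed-size audio feature vector.

Convolutions use circular (wrap) padding, so the extractor is exactly
invariant to circular time shifts that are multiples of the cumulative
pooling stride.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from . import nn
from .nn import Tensor
from .audio_preproc import AudioClip
from .image_features import FeatureVector


@dataclass(frozen=True)
class AudioCNNConfig:
    input_len: int = 16000          # samples fed to the CNN
    sample_rate: int = 16000        # rate those samples are at
    channels: tuple[int, int, int] = (16, 32, 64)
    kernel_sizes: tuple[int, int, int] = (9, 9, 9)
    pool_factors: tuple[int, int, int] = (4, 4, 4)
    dilation: int = 2               # third layer only
    output_dim: int = 128

    def __post_init__(self):
        if self.dilation < 1:
            raise ValueError("dilation must be >= 1")
        if self.input_len < self.cumulative_stride():
            raise ValueError("input shorter than one pooled receptive field")

    def cumulative_stride(self) -> int:
        s = 1
        for p in self.pool_factors:
            s *= p
        return s


def receptive_field(cfg: AudioCNNConfig) -> int:
    """Receptive field (in input samples) of one output time step.

    Closed form for stride-1 convs interleaved with pools: each conv with
    kernel k and dilation d adds d·(k−1)·jump samples; each pool of factor
    p adds (p−1)·jump and multiplies the jump by p.
    """
    rf, jump = 1, 1
    dilations = (1, 1, cfg.dilation)
    for k, p, d in zip(cfg.kernel_sizes, cfg.pool_factors, dilations):
        rf += d * (k - 1) * jump
        rf += (p - 1) * jump
        jump *= p
    return rf


def prepare_waveform(clip: AudioClip, cfg: AudioCNNConfig) -> np.ndarray:
    """Resample to cfg.sample_rate, then centre-crop or zero-pad to input_len."""
    x = clip.samples
    if clip.sample_rate != cfg.sample_rate:
        x = sp_signal.resample_poly(x, cfg.sample_rate, clip.sample_rate)
    n = len(x)
    if n > cfg.input_len:
        start = (n - cfg.input_len) // 2
        x = x[start:start + cfg.input_len]
    elif n < cfg.input_len:
        pad = cfg.input_len - n
        x = np.pad(x, (pad // 2, pad - pad // 2))
    return np.asarray(x, dtype=np.float64)


class AudioEncoder(nn.Module):
    """conv->ReLU->pool ×3 (third conv dilated) -> global average -> linear."""

    def __init__(self, cfg: AudioCNNConfig, rng: np.random.Generator):
        self.cfg = cfg
        c1, c2, c3 = cfg.channels
        k1, k2, k3 = cfg.kernel_sizes
        self.conv1 = nn.Conv1d(1, c1, k1, rng)
        self.conv2 = nn.Conv1d(c1, c2, k2, rng)
        self.conv3 = nn.Conv1d(c2, c3, k3, rng, dilation=cfg.dilation)
        self.head = nn.Linear(c3, cfg.output_dim, rng)

    def __call__(self, waves: np.ndarray) -> Tensor:
        """(B, L) waveform batch -> (B, output_dim) features."""
        p1, p2, p3 = self.cfg.pool_factors
        x = Tensor(waves[:, None, :])
        x = nn.avg_pool1d(nn.relu(self.conv1(x)), p1)
        x = nn.avg_pool1d(nn.relu(self.conv2(x)), p2)
        x = nn.avg_pool1d(nn.relu(self.conv3(x)), p3)
        x = x.mean(axis=2)  # global average over time -> (B, C3)
        return self.head(x)


def encode_audio(clip: AudioClip, encoder: AudioEncoder) -> FeatureVector:
    """Single-clip convenience wrapper returning a FeatureVector."""
    wave = prepare_waveform(clip, encoder.cfg)
    feat = encoder(wave[None, :])
    return FeatureVector(values=feat.data[0].copy(), modality="audio")
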