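"""ViT-style image feature extractor.

The preprocessed thermal image is cut into fixed-size patches, each patch
is linearly embedded (equivalent to a convolution whose kernel and stride
equal the patch size), a learned positional table is added, and the token
sequence runs through pre-norm transformer encoder layers:

    LN -> multi-head self-attention -> residual -> LN -> FFN -> residual

with attention softmax(QKᵀ/√d_k)·V and FFN(x) = ReLU(xW₁+b₁)W₂+b₂.
Tokens are mean-pooled into a single feature vector of dimension D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor


@dataclass(frozen=True)
class PatchGridSpec:
    """Patch grid geometry: image (H, W) cut into (P_H, P_W) patches."""

    image_size: tuple[int, int] = (32, 32)
    patch_size: tuple[int, int] = (8, 8)
    embed_dim: int = 64

    def __post_init__(self):
        H, W = self.image_size
        ph, pw = self.patch_size
        if H % ph or W % pw:
            raise ValueError(
                f"patch {self.patch_size} does not divide image {self.image_size}")

    @property
    def num_patches(self) -> int:
        H, W = self.image_size
        ph, pw = self.patch_size
        return (H * W) // (ph * pw)

    @property
    def patch_dim(self) -> int:
        return self.patch_size[0] * self.patch_size[1]


@dataclass(frozen=True)
class EncoderConfig:
    depth: int = 2
    num_heads: int = 2
    ffn_hidden: int = 128

    def d_k(self, embed_dim: int) -> int:
        if embed_dim % self.num_heads:
            raise ValueError("embed_dim must be divisible by num_heads")
        return embed_dim // self.num_heads


@dataclass
class FeatureVector:
    """Pooled single-sample feature with its source modality."""

    values: np.ndarray
    modality: str

    @property
    def dim(self) -> int:
        return int(self.values.shape[-1])


# ---------------------------------------------------------------------
# functional forms (NumPy, used directly in analyses and tests)
# ---------------------------------------------------------------------

def extract_patches(img: np.ndarray, spec: PatchGridSpec) -> np.ndarray:
    """(H, W) image -> (N, P_H·P_W) row-major patch matrix."""
    H, W = spec.image_size
    ph, pw = spec.patch_size
    if img.shape != (H, W):
        raise ValueError(f"image shape {img.shape} != spec {spec.image_size}")
    return (img.reshape(H // ph, ph, W // pw, pw)
               .transpose(0, 2, 1, 3)
               .reshape(spec.num_patches, ph * pw))


def patchify_embed(img: np.ndarray, spec: PatchGridSpec,
                   weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Patch embedding: (N, P·P) patches times (P·P, D) kernel plus bias."""
    return extract_patches(img, spec) @ weight + bias


def add_positional(tokens: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Elementwise sum of token and positional embeddings (shapes match)."""
    if tokens.shape != pos.shape:
        raise ValueError(f"shape mismatch {tokens.shape} vs {pos.shape}")
    return tokens + pos


def self_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
                   d_k: int, return_weights: bool = False):
    """softmax(QKᵀ/√d_k)·V; each output row is a convex mix of V rows."""
    if d_k <= 0:
        raise ValueError("d_k must be positive")
    scores = Q @ K.T / np.sqrt(d_k)
    scores -= scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    A = e / e.sum(axis=-1, keepdims=True)
    out = A @ V
    return (out, A) if return_weights else out


def ffn(x: np.ndarray, W1: np.ndarray, b1: np.ndarray,
        W2: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """FFN(x) = ReLU(xW₁+b₁)W₂+b₂."""
    return np.maximum(x @ W1 + b1, 0.0) @ W2 + b2


# ---------------------------------------------------------------------
# trainable encoder
# ---------------------------------------------------------------------

class MultiHeadSelfAttention(nn.Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.heads = heads
        self.dk = dim // heads
        self.qkv = nn.Linear(dim, 3 * dim, rng)
        self.proj = nn.Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, N, D = x.shape
        h, dk = self.heads, self.dk
        qkv = self.qkv(x).reshape(B, N, 3, h, dk).transpose(2, 0, 3, 1, 4)
        qkv_flat = qkv.reshape(3, B * h, N, dk)
        q = _index0(qkv_flat, 0)
        k = _index0(qkv_flat, 1)
        v = _index0(qkv_flat, 2)
        scores = nn.matmul(q, k.transpose(0, 2, 1)) * (1.0 / np.sqrt(dk))
        attn = nn.softmax(scores, axis=-1)
        out = nn.matmul(attn, v)                       # (B*h, N, dk)
        out = out.reshape(B, h, N, dk).transpose(0, 2, 1, 3).reshape(B, N, D)
        return self.proj(out)


def _index0(t: Tensor, i: int) -> Tensor:
    """Differentiable selection along axis 0."""
    out = nn._make(t.data[i], (t,))

    def _bw():
        if t.requires_grad:
            g = np.zeros_like(t.data)
            g[i] = out.grad
            t._accum(g)

    nn._set_backward(out, _bw)
    return out


class EncoderLayer(nn.Module):
    """Pre-norm transformer block: LN->MHA->res, LN->FFN->res."""

    def __init__(self, dim: int, cfg: EncoderConfig, rng: np.random.Generator):
        self.ln1 = nn.LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, cfg.num_heads, rng)
        self.ln2 = nn.LayerNorm(dim)
        self.fc1 = nn.Linear(dim, cfg.ffn_hidden, rng)
        self.fc2 = nn.Linear(cfg.ffn_hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.fc2(nn.relu(self.fc1(self.ln2(x))))


class ImageEncoder(nn.Module):
    """Patch embedding + positional table + stacked encoder layers."""

    def __init__(self, spec: PatchGridSpec, cfg: EncoderConfig,
                 rng: np.random.Generator):
        self.spec = spec
        self.cfg = cfg
        D = spec.embed_dim
        self.embed = nn.Linear(spec.patch_dim, D, rng)
        self.pos = nn.Parameter(rng.normal(0.0, 0.02, (spec.num_patches, D)))
        self.layers = [EncoderLayer(D, cfg, rng) for _ in range(cfg.depth)]
        self.out_norm = nn.LayerNorm(D)

    def tokens(self, imgs: np.ndarray) -> Tensor:
        """(B, H, W) image batch -> (B, N, D) embedded tokens + positions."""
        B = imgs.shape[0]
        H, W = self.spec.image_size
        ph, pw = self.spec.patch_size
        patches = (imgs.reshape(B, H // ph, ph, W // pw, pw)
                       .transpose(0, 1, 3, 2, 4)
                       .reshape(B, self.spec.num_patches, ph * pw))
        return self.embed(Tensor(patches)) + self.pos

    def __call__(self, imgs: np.ndarray) -> Tensor:
        x = self.tokens(imgs)
        for layer in self.layers:
            x = layer(x)
        return self.out_norm(x).mean(axis=1)  # (B, D) token mean-pool


def encode_image(img: np.ndarray, encoder: ImageEncoder) -> FeatureVector:
    """Single-image convenience wrapper returning a FeatureVector."""
    feat = encoder(img[None, :, :])
    return FeatureVector(values=feat.data[0].copy(), modality="image")
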