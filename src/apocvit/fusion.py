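"""Adaptive cross-attention fusion of image and audio features.

The two pooled feature vectors X (image) and Y (audio) are concatenated
into Z = [X, Y], pushed through a ReLU MLP, and a sigmoid output head
produces a per-sample attention weight A ∈ [0, 1] on the image modality:

    H    = ReLU(W_in·Z + b_in)
    H(k) = ReLU(W_k·H(k−1) + b_k)      (k MLP layers)
    A    = sigmoid(W_out·H(k) + b_out)

The fused representation is the convex combination
fused = A·proj_img(X) + (1−A)·proj_aud(Y), which makes the fixed-weight
baselines (0.5/0.5, 0.7/0.3, 0.3/0.7) exact special cases, along with
plain concatenation for the simplest baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .image_features import FeatureVector


@dataclass
class FusionResult:
    """Fused feature plus the attention weight A on the image modality."""

    fused: np.ndarray
    attention: float

    def __post_init__(self):
        if not (0.0 <= self.attention <= 1.0):
            raise ValueError("attention weight must lie in [0, 1]")


class CrossAttentionFusion(nn.Module):
    """Learned scalar-gate fusion with linear projections to a common dim.

    ``mlp_depth`` counts the hidden ReLU layers after the input map;
    ``fused_dim`` is the common dimension both modalities are projected to.
    With ``vector_gate=True`` the head emits one weight per fused dimension
    instead of a scalar.
    """

    def __init__(self, dim_img: int, dim_aud: int, rng: np.random.Generator,
                 hidden: int = 128, mlp_depth: int = 2, fused_dim: int = 128,
                 vector_gate: bool = False):
        self.input_map = nn.Linear(dim_img + dim_aud, hidden, rng)
        self.mlp = [nn.Linear(hidden, hidden, rng) for _ in range(mlp_depth)]
        self.output_map = nn.Linear(hidden, fused_dim if vector_gate else 1, rng)
        # zero-init the gate head: A starts exactly at the neutral 0.5, so
        # adaptive fusion begins as the balanced mixture and departs from it
        # only where the gradient favours gating
        self.output_map.W.data[:] = 0.0
        self.proj_img = nn.Linear(dim_img, fused_dim, rng)
        self.proj_aud = nn.Linear(dim_aud, fused_dim, rng)
        self.fused_dim = fused_dim
        self.vector_gate = vector_gate

    def attention(self, X: Tensor, Y: Tensor) -> Tensor:
        """A ∈ (0,1): weight on the image modality, (B,1) or (B,fused_dim).

        The gate reads *detached* features (stop-gradient): it routes
        between modalities without distorting representation learning, so
        the encoders receive exactly the mixture gradients and the gate
        parameters alone learn the weighting.
        """
        z = nn.concat([Tensor(X.data), Tensor(Y.data)], axis=-1)
        h = nn.relu(self.input_map(z))
        for layer in self.mlp:
            h = nn.relu(layer(h))
        return nn.sigmoid(self.output_map(h))

    def adaptive(self, X: Tensor, Y: Tensor) -> tuple[Tensor, Tensor]:
        A = self.attention(X, Y)
        fused = A * self.proj_img(X) + (1.0 - A) * self.proj_aud(Y)
        return fused, A

    def fixed(self, X: Tensor, Y: Tensor, w_img: float, w_aud: float) -> Tensor:
        if w_img < 0 or w_aud < 0 or abs(w_img + w_aud - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")
        return w_img * self.proj_img(X) + (1.0 - w_img) * self.proj_aud(Y)


def adaptive_fuse(X: FeatureVector, Y: FeatureVector,
                  params: CrossAttentionFusion) -> FusionResult:
    """Single-sample adaptive fusion (batch path: params.adaptive)."""
    fused, A = params.adaptive(Tensor(X.values[None, :]),
                               Tensor(Y.values[None, :]))
    a = float(A.data.mean())
    return FusionResult(fused=fused.data[0].copy(), attention=a)


def fixed_fuse(X: FeatureVector, Y: FeatureVector, w_img: float, w_aud: float,
               params: CrossAttentionFusion) -> FusionResult:
    fused = params.fixed(Tensor(X.values[None, :]), Tensor(Y.values[None, :]),
                         w_img, w_aud)
    return FusionResult(fused=fused.data[0].copy(), attention=w_img)


def concat_fuse(X: FeatureVector, Y: FeatureVector) -> FeatureVector:
    """Plain concatenation, image block first (fixed convention)."""
    return FeatureVector(values=np.concatenate([X.values, Y.values]),
                         modality="fused")
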