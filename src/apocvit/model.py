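"""Full multimodal model: ViT image branch + CNN audio branch + fusion +
DenseNet-SE classifier, with the fusion/ablation conditions selectable by
name (image_only, audio_only, fixed weights, concat, adaptive, adaptive+SE).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .image_features import PatchGridSpec, EncoderConfig, ImageEncoder
from .audio_features import AudioCNNConfig, AudioEncoder
from .fusion import CrossAttentionFusion
from .backbone_classifier import DenseNetSEConfig, DenseNetSE

#: condition name -> (fusion mode, extra) used by the ablation harness
CONDITIONS = {
    "image_only": ("fixed", (1.0, 0.0)),
    "audio_only": ("fixed", (0.0, 1.0)),
    "fixed_0.5_0.5": ("fixed", (0.5, 0.5)),
    "fixed_0.7_0.3": ("fixed", (0.7, 0.3)),
    "fixed_0.3_0.7": ("fixed", (0.3, 0.7)),
    "concat": ("concat", None),
    "adaptive": ("adaptive", None),          # adaptive fusion, plain DenseNet
    "adaptive_se": ("adaptive", None),       # adaptive fusion + SE blocks
}


@dataclass
class ApoCvitConfig:
    patch_spec: PatchGridSpec = field(default_factory=PatchGridSpec)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    audio: AudioCNNConfig = field(default_factory=AudioCNNConfig)
    backbone: DenseNetSEConfig = field(default_factory=DenseNetSEConfig)
    fusion_mode: str = "adaptive"            # adaptive | fixed | concat
    fixed_weights: tuple[float, float] = (0.5, 0.5)
    fusion_hidden: int = 128
    fusion_mlp_depth: int = 2

    @classmethod
    def for_condition(cls, condition: str, **kwargs) -> "ApoCvitConfig":
        """Build the config for a named ablation condition."""
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}; "
                             f"choose from {sorted(CONDITIONS)}")
        mode, extra = CONDITIONS[condition]
        cfg = cls(**kwargs)
        cfg.fusion_mode = mode
        if mode == "fixed":
            cfg.fixed_weights = extra
        use_se = condition == "adaptive_se"
        cfg.backbone = DenseNetSEConfig(
            reshape=cfg.backbone.reshape,
            stem_channels=cfg.backbone.stem_channels,
            block_layers=cfg.backbone.block_layers,
            growth_rate=cfg.backbone.growth_rate,
            se_reduction=cfg.backbone.se_reduction,
            num_classes=cfg.backbone.num_classes,
            use_se=use_se,
        )
        if mode == "concat":
            # concatenated features are wider; double the reshape channels
            c, h, w = cfg.backbone.reshape
            cfg.backbone = DenseNetSEConfig(
                reshape=(2 * c, h, w),
                stem_channels=cfg.backbone.stem_channels,
                block_layers=cfg.backbone.block_layers,
                growth_rate=cfg.backbone.growth_rate,
                se_reduction=cfg.backbone.se_reduction,
                num_classes=cfg.backbone.num_classes,
                use_se=use_se,
            )
        return cfg


class ApoCvit(nn.Module):
    """End-to-end multimodal estrus classifier."""

    def __init__(self, cfg: ApoCvitConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.image_encoder = ImageEncoder(cfg.patch_spec, cfg.encoder, rng)
        self.audio_encoder = AudioEncoder(cfg.audio, rng)
        fused_dim = cfg.backbone.fused_dim
        if cfg.fusion_mode == "concat":
            if fused_dim % 2:
                raise ValueError("concat mode needs an even fused dim")
            proj_dim = fused_dim // 2
        else:
            proj_dim = fused_dim
        self.fusion = CrossAttentionFusion(
            cfg.patch_spec.embed_dim, cfg.audio.output_dim, rng,
            hidden=cfg.fusion_hidden, mlp_depth=cfg.fusion_mlp_depth,
            fused_dim=proj_dim)
        self.backbone = DenseNetSE(cfg.backbone, rng)

    def fuse(self, X: Tensor, Y: Tensor) -> tuple[Tensor, np.ndarray | None]:
        mode = self.cfg.fusion_mode
        if mode == "adaptive":
            fused, A = self.fusion.adaptive(X, Y)
            return fused, A.data.copy()
        if mode == "fixed":
            w_img, w_aud = self.cfg.fixed_weights
            return self.fusion.fixed(X, Y, w_img, w_aud), None
        if mode == "concat":
            # still pass through the projections so dims line up, then stack
            return nn.concat([self.fusion.proj_img(X),
                              self.fusion.proj_aud(Y)], axis=-1), None
        raise ValueError(f"unknown fusion mode {mode!r}")

    def __call__(self, imgs: np.ndarray, waves: np.ndarray) -> Tensor:
        # a modality with fixed weight exactly 0 contributes exactly zero,
        # so its encoder can be skipped without changing the output
        if self.cfg.fusion_mode == "fixed" and self.cfg.fixed_weights[1] == 0:
            fused = self.fusion.proj_img(self.image_encoder(imgs))
            return self.backbone(fused)
        if self.cfg.fusion_mode == "fixed" and self.cfg.fixed_weights[0] == 0:
            fused = self.fusion.proj_aud(self.audio_encoder(waves))
            return self.backbone(fused)
        X = self.image_encoder(imgs)
        Y = self.audio_encoder(waves)
        fused, _ = self.fuse(X, Y)
        return self.backbone(fused)

    def predict(self, imgs: np.ndarray, waves: np.ndarray,
                batch_size: int = 64) -> np.ndarray:
        """Hard class predictions without building gradient state."""
        out = []
        with nn.no_grad():
            for i in range(0, len(imgs), batch_size):
                logits = self(imgs[i:i + batch_size], waves[i:i + batch_size])
                out.append(np.argmax(logits.data, axis=1))
        return np.concatenate(out) if out else np.array([], dtype=int)

    def attention_weights(self, imgs: np.ndarray, waves: np.ndarray) -> np.ndarray:
        """Per-sample fusion weight A on the image modality (adaptive mode)."""
        with nn.no_grad():
            X = self.image_encoder(imgs)
            Y = self.audio_encoder(waves)
            return self.fusion.attention(X, Y).data.ravel().copy()


def save_checkpoint(model: ApoCvit, path: str | Path) -> None:
    """Serialise weights + config as portable JSON (small desk-scale models)."""
    payload = {
        "config": _cfg_to_dict(model.cfg),
        "weights": [p.data.tolist() for p in model.parameters()],
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> ApoCvit:
    payload = json.loads(Path(path).read_text())
    cfg = _cfg_from_dict(payload["config"])
    model = ApoCvit(cfg, np.random.default_rng(0))
    params = model.parameters()
    for p, w in zip(params, payload["weights"]):
        p.data = np.array(w, dtype=nn.DTYPE).reshape(p.data.shape)
    return model


def _cfg_to_dict(cfg: ApoCvitConfig) -> dict:
    return {
        "patch_spec": asdict(cfg.patch_spec),
        "encoder": asdict(cfg.encoder),
        "audio": asdict(cfg.audio),
        "backbone": asdict(cfg.backbone),
        "fusion_mode": cfg.fusion_mode,
        "fixed_weights": list(cfg.fixed_weights),
        "fusion_hidden": cfg.fusion_hidden,
        "fusion_mlp_depth": cfg.fusion_mlp_depth,
    }


def _cfg_from_dict(d: dict) -> ApoCvitConfig:
    def tup(x):
        return tuple(x) if isinstance(x, list) else x

    ps = {k: tup(v) for k, v in d["patch_spec"].items()}
    au = {k: tup(v) for k, v in d["audio"].items()}
    bb = {k: tup(v) for k, v in d["backbone"].items()}
    return ApoCvitConfig(
        patch_spec=PatchGridSpec(**ps),
        encoder=EncoderConfig(**d["encoder"]),
        audio=AudioCNNConfig(**au),
        backbone=DenseNetSEConfig(**bb),
        fusion_mode=d["fusion_mode"],
        fixed_weights=tuple(d["fixed_weights"]),
        fusion_hidden=d["fusion_hidden"],
        fusion_mlp_depth=d["fusion_mlp_depth"],
    )
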