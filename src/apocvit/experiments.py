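"""Desk-scale synthetic experiments: fusion ablation and null calibration.

These are the standard study conditions the package's stochastic checks
run under. Everything is sized for a single CPU: 96×96 synthetic images
resized to 32×32 for the ViT (patch 8, D=64, depth 2), audio band-pass
filtered and resampled to 4 kHz for the CNN, and a narrow DenseNet-SE.
The ablation harness reuses one preprocessed dataset and re-derives each
run's initialisation and batch order from the run seed, so per-seed
differences between conditions reflect architecture only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .core_data import split_indices
from .image_features import PatchGridSpec, EncoderConfig
from .audio_features import AudioCNNConfig
from .backbone_classifier import DenseNetSEConfig
from .model import ApoCvitConfig
from .synthetic_data import SyntheticSpec, generate_arrays, oracle_features
from .train_eval import (ModelDataset, TrainConfig, prepare_dataset, subset,
                         run_ablation)

#: default fusion conditions compared in the synthetic ablation
DEFAULT_CONDITIONS = ["image_only", "audio_only", "fixed_0.5_0.5",
                      "adaptive"]


def small_config() -> ApoCvitConfig:
    """Reduced model for CPU-scale experiments (D=64, depth 2)."""
    return ApoCvitConfig(
        patch_spec=PatchGridSpec(image_size=(32, 32), patch_size=(4, 4),
                                 embed_dim=64),
        encoder=EncoderConfig(depth=2, num_heads=2, ffn_hidden=128),
        audio=AudioCNNConfig(input_len=2000, sample_rate=2000,
                             channels=(8, 16, 32), kernel_sizes=(9, 9, 9),
                             pool_factors=(4, 4, 4), dilation=2,
                             output_dim=64),
        backbone=DenseNetSEConfig(reshape=(4, 4, 4), stem_channels=8,
                                  block_layers=(2, 2, 2), growth_rate=8,
                                  se_reduction=4),
        fusion_hidden=64,
        fusion_mlp_depth=2,
    )


def small_train_config(seed: int = 0, epochs: int = 12) -> TrainConfig:
    return TrainConfig(batch_size=16, epochs=epochs, learning_rate=0.001,
                       lr_drop_factor=0.1, lr_patience=5, seed=seed)


def build_experiment_data(spec: SyntheticSpec, cfg: ApoCvitConfig,
                          split_seed: int = 0
                          ) -> tuple[ModelDataset, ModelDataset, ModelDataset]:
    """Generate, preprocess and 6:2:2-split one synthetic dataset."""
    raw = generate_arrays(spec)
    ds = prepare_dataset(raw["images"], raw["audio"], raw["labels"], cfg,
                         spec.sample_rate, sample_ids=raw["sample_ids"])
    tr, va, te = split_indices(ds.labels, (0.6, 0.2, 0.2), split_seed)
    return subset(ds, tr), subset(ds, va), subset(ds, te)


def run_fusion_ablation(seed: int = 0, n_pairs: int = 400, epochs: int = 12,
                        n_seeds: int = 10,
                        conditions: list[str] | None = None) -> pd.DataFrame:
    """Train each fusion condition over ``n_seeds`` runs on one synthetic
    dataset; returns the per-run P/R/F1 table."""
    cfg = small_config()
    spec = SyntheticSpec(n_pairs=n_pairs, seed=seed)
    train_ds, val_ds, test_ds = build_experiment_data(spec, cfg, seed)
    tc = small_train_config(seed=seed, epochs=epochs)
    run_seeds = [seed + 1000 * k for k in range(n_seeds)]
    return run_ablation(conditions or DEFAULT_CONDITIONS, train_ds, val_ds,
                        test_ds, tc, seeds=run_seeds, base_cfg=cfg)


def oracle_accuracy(spec: SyntheticSpec, seed: int = 0,
                    features: str = "both") -> float:
    """Accuracy of a logistic fit on the two hand-crafted oracle features
    (warm-region intensity, call-band power ratio), 6:2:2 train/test."""
    raw = generate_arrays(spec)
    X = oracle_features(raw["images"], raw["audio"], spec.sample_rate)
    if features == "image":
        X = X[:, :1]
    elif features == "audio":
        X = X[:, 1:]
    y = raw["labels"]
    tr, _, te = split_indices(y, (0.6, 0.2, 0.2), seed)
    clf = make_pipeline(StandardScaler(),
                        LogisticRegression(max_iter=1000))
    clf.fit(X[tr], y[tr])
    return float(clf.score(X[te], y[te]))


def null_calibration(seed: int = 0, n_pairs: int = 200,
                     n_seeds: int = 10) -> dict:
    """Expected accuracy with zero class effect: both classes share the
    same image and audio distributions, so any classifier sits at 50%
    up to Monte-Carlo error."""
    accs = []
    for k in range(n_seeds):
        spec = SyntheticSpec(n_pairs=n_pairs, seed=seed + 7919 * k).null()
        accs.append(oracle_accuracy(spec, seed=seed + k))
    accs = np.array(accs)
    n_test = int(n_pairs * 0.2)
    return {
        "accuracies": accs,
        "mean_accuracy": float(accs.mean()),
        # binomial Monte-Carlo error of the mean over seeds
        "mc_error": float(0.5 / np.sqrt(n_test * n_seeds)),
    }
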