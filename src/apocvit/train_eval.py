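"""Training loop, evaluation metrics and the ablation harness.

Metrics follow the usual binary-classification definitions with estrus as
the positive class:

    P  = TP / (TP + FP) × 100%
    R  = TP / (TP + FN) × 100%
    F1 = 2·P·R / (P + R)

reported as percentages rounded half-up to two decimals (raw values are
kept alongside). Training uses Adam with a ReduceLROnPlateau schedule
monitored on validation loss: after ``patience`` epochs without
improvement the learning rate is multiplied by ``factor``.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from . import nn
from .core_data import LabeledPair, ESTRUS
from .image_preproc import load_image, preprocess_image
from .audio_preproc import (AudioClip, ChebyshevBandpassSpec, load_wav,
                            denoise_audio)
from .audio_features import prepare_waveform
from .model import ApoCvit, ApoCvitConfig, CONDITIONS


# ---------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.total if self.total else 0.0


@dataclass(frozen=True)
class ClassificationMetrics:
    precision: float     # percent, rounded half-up to 2 decimals
    recall: float
    f1: float
    precision_raw: float = 0.0
    recall_raw: float = 0.0
    f1_raw: float = 0.0
    degenerate: bool = False


def _round2(x: float) -> float:
    return float(decimal.Decimal(repr(x)).quantize(
        decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP))


def compute_metrics(c: ConfusionCounts) -> ClassificationMetrics:
    """Precision/recall/F1 from confusion counts (estrus = positive).

    Degenerate denominators yield 0 and set the ``degenerate`` flag.
    """
    degenerate = False
    if c.tp + c.fp == 0:
        p, degenerate = 0.0, True
    else:
        p = 100.0 * c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        r, degenerate = 0.0, True
    else:
        r = 100.0 * c.tp / (c.tp + c.fn)
    if p + r == 0:
        f1, degenerate = 0.0, True
    else:
        f1 = 2.0 * p * r / (p + r)
    return ClassificationMetrics(
        precision=_round2(p), recall=_round2(r), f1=_round2(f1),
        precision_raw=p, recall_raw=r, f1_raw=f1, degenerate=degenerate)


def f1_from_pr(p: float, r: float) -> float:
    """Harmonic mean of precision and recall (both in percent)."""
    if p < 0 or r < 0 or p > 100 or r > 100:
        raise ValueError("P and R must be percentages in [0, 100]")
    if p + r == 0:
        raise ValueError("P + R must be positive")
    return _round2(2.0 * p * r / (p + r))


def confusion_from_predictions(y_true: np.ndarray,
                               y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == ESTRUS) & (y_pred == ESTRUS))),
        fp=int(np.sum((y_true != ESTRUS) & (y_pred == ESTRUS))),
        fn=int(np.sum((y_true == ESTRUS) & (y_pred != ESTRUS))),
        tn=int(np.sum((y_true != ESTRUS) & (y_pred != ESTRUS))),
    )


# ---------------------------------------------------------------------
# training configuration / scheduler
# ---------------------------------------------------------------------

@dataclass
class TrainConfig:
    batch_size: int = 16
    epochs: int = 100
    learning_rate: float = 0.001
    lr_drop_factor: float = 0.1
    lr_patience: int = 5
    scheduler: str = "plateau"    # or "step" (fixed decay every patience epochs)
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.lr_drop_factor < 1):
            raise ValueError("lr_drop_factor must lie in (0, 1)")
        if min(self.batch_size, self.epochs, self.lr_patience) <= 0:
            raise ValueError("batch_size, epochs, patience must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class ReduceLROnPlateau:
    """Multiply lr by ``factor`` after ``patience`` epochs without a new
    best monitored value (strict improvement, no threshold)."""

    def __init__(self, optimizer: nn.Adam, factor: float = 0.1,
                 patience: int = 5):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.best = np.inf
        self.num_bad = 0
        self.drops: list[int] = []   # epoch numbers (1-based) where lr dropped
        self._epoch = 0

    def step(self, metric: float) -> None:
        self._epoch += 1
        if metric < self.best:
            self.best = metric
            self.num_bad = 0
        else:
            self.num_bad += 1
            if self.num_bad >= self.patience:
                self.optimizer.lr *= self.factor
                self.drops.append(self._epoch)
                self.num_bad = 0


# ---------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------

@dataclass
class ModelDataset:
    """Model-ready arrays: preprocessed images, waveforms and labels."""

    images: np.ndarray   # (n, H, W) float
    waves: np.ndarray    # (n, L) float
    labels: np.ndarray   # (n,) int
    sample_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.labels)


def _resize_image(img: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Block-free bilinear resize via ndimage zoom."""
    from scipy.ndimage import zoom
    h, w = img.shape
    return zoom(img, (size[0] / h, size[1] / w), order=1)


def prepare_dataset(images: np.ndarray, audio: np.ndarray, labels: np.ndarray,
                    cfg: ApoCvitConfig, sample_rate: int,
                    sample_ids: list[str] | None = None,
                    denoise: bool = True,
                    band: ChebyshevBandpassSpec | None = None) -> ModelDataset:
    """Run both preprocessing pipelines and shape arrays for the model."""
    size = cfg.patch_spec.image_size
    band = band or ChebyshevBandpassSpec(
        band=(100.0, min(4000.0, sample_rate / 2 - 1)))
    imgs, waves = [], []
    for im, wv in zip(images, audio):
        im = preprocess_image(im, denoise=denoise)
        if im.shape != size:
            im = _resize_image(im, size)
        imgs.append(im)
        clip = AudioClip(wv, sample_rate)
        if denoise:
            clip = denoise_audio(clip, band)
        waves.append(prepare_waveform(clip, cfg.audio))
    return ModelDataset(images=np.stack(imgs), waves=np.stack(waves),
                        labels=np.asarray(labels, dtype=int),
                        sample_ids=list(sample_ids or []))


def load_pairs(pairs: list[LabeledPair], cfg: ApoCvitConfig,
               denoise: bool = True) -> ModelDataset:
    """Load a manifest's files from disk and preprocess them."""
    images, audio, labels, ids, rate = [], [], [], [], None
    for p in pairs:
        images.append(load_image(p.image_path))
        clip = load_wav(p.audio_path)
        rate = clip.sample_rate
        audio.append(clip.samples)
        labels.append(p.label)
        ids.append(p.sample_id)
    return prepare_dataset(np.stack(images), np.stack(audio),
                           np.array(labels), cfg, rate,
                           sample_ids=ids, denoise=denoise)


def subset(ds: ModelDataset, idx: np.ndarray) -> ModelDataset:
    return ModelDataset(images=ds.images[idx], waves=ds.waves[idx],
                        labels=ds.labels[idx],
                        sample_ids=[ds.sample_ids[i] for i in idx]
                        if ds.sample_ids else [])


# ---------------------------------------------------------------------
# training / evaluation
# ---------------------------------------------------------------------

@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    lr_drops: list[int] = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, len(self.train_loss) + 1),
            "lr": self.lr,
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
        })


def _eval_loss(model: ApoCvit, ds: ModelDataset, batch: int = 64) -> float:
    losses, weights = [], []
    with nn.no_grad():
        for i in range(0, len(ds), batch):
            logits = model(ds.images[i:i + batch], ds.waves[i:i + batch])
            loss = nn.cross_entropy(logits, ds.labels[i:i + batch])
            losses.append(float(loss.data))
            weights.append(len(ds.labels[i:i + batch]))
    return float(np.average(losses, weights=weights))


def train_model(model: ApoCvit, train_ds: ModelDataset, val_ds: ModelDataset,
                tc: TrainConfig, verbose: bool = False
                ) -> tuple[list[np.ndarray], TrainHistory]:
    """Seeded Adam training with plateau LR schedule; returns the
    best-validation-loss weights and the per-epoch history."""
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise ValueError("empty split")
    rng = np.random.default_rng(tc.seed)
    opt = nn.Adam(model.parameters(), lr=tc.learning_rate)
    sched = ReduceLROnPlateau(opt, tc.lr_drop_factor, tc.lr_patience)
    hist = TrainHistory()
    best_val, best_state = np.inf, model.copy_state()
    for epoch in range(1, tc.epochs + 1):
        order = rng.permutation(len(train_ds))
        epoch_losses = []
        for i in range(0, len(order), tc.batch_size):
            idx = order[i:i + tc.batch_size]
            model.zero_grad()
            logits = model(train_ds.images[idx], train_ds.waves[idx])
            loss = nn.cross_entropy(logits, train_ds.labels[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        val_loss = _eval_loss(model, val_ds)
        hist.train_loss.append(float(np.mean(epoch_losses)))
        hist.val_loss.append(val_loss)
        hist.lr.append(opt.lr)
        if tc.scheduler == "plateau":
            sched.step(val_loss)
        elif epoch % tc.lr_patience == 0:   # fixed step decay
            opt.lr *= tc.lr_drop_factor
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.copy_state()
            hist.best_epoch = epoch
        if verbose:
            print(f"epoch={epoch} lr={opt.lr:.2e} "
                  f"train_loss={hist.train_loss[-1]:.4f} val_loss={val_loss:.4f}")
    hist.lr_drops = list(sched.drops)
    model.load_state_dict(best_state)
    return best_state, hist


def evaluate(model: ApoCvit, ds: ModelDataset
             ) -> tuple[ConfusionCounts, ClassificationMetrics]:
    preds = model.predict(ds.images, ds.waves)
    counts = confusion_from_predictions(ds.labels, preds)
    return counts, compute_metrics(counts)


# ---------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------

def run_condition(condition: str, train_ds: ModelDataset, val_ds: ModelDataset,
                  test_ds: ModelDataset, tc: TrainConfig,
                  base_cfg: ApoCvitConfig | None = None) -> dict:
    """Train and evaluate one named fusion condition."""
    kwargs = {}
    if base_cfg is not None:
        kwargs = dict(patch_spec=base_cfg.patch_spec, encoder=base_cfg.encoder,
                      audio=base_cfg.audio, backbone=base_cfg.backbone,
                      fusion_hidden=base_cfg.fusion_hidden,
                      fusion_mlp_depth=base_cfg.fusion_mlp_depth)
    cfg = ApoCvitConfig.for_condition(condition, **kwargs)
    model = ApoCvit(cfg, np.random.default_rng(tc.seed))
    _, hist = train_model(model, train_ds, val_ds, tc)
    counts, metrics = evaluate(model, test_ds)
    return {
        "condition": condition,
        "seed": tc.seed,
        "precision": metrics.precision,
        "recall": metrics.recall,
        "f1": metrics.f1,
        "accuracy": _round2(counts.accuracy),
        "counts": counts,
        "history": hist,
    }


def run_ablation(conditions: list[str], train_ds: ModelDataset,
                 val_ds: ModelDataset, test_ds: ModelDataset,
                 tc: TrainConfig, seeds: list[int] | None = None,
                 base_cfg: ApoCvitConfig | None = None) -> pd.DataFrame:
    """Train every condition under identical seeds and data order.

    Each (condition, seed) run re-derives its shuffling and initial
    weights from the same seed, so per-seed deltas between conditions are
    attributable to the architecture alone.
    """
    unknown = [c for c in conditions if c not in CONDITIONS]
    if unknown:
        raise ValueError(f"unknown condition names: {unknown}")
    seeds = seeds if seeds is not None else [tc.seed]
    rows = []
    for seed in seeds:
        tc_run = TrainConfig(batch_size=tc.batch_size, epochs=tc.epochs,
                             learning_rate=tc.learning_rate,
                             lr_drop_factor=tc.lr_drop_factor,
                             lr_patience=tc.lr_patience,
                             scheduler=tc.scheduler, seed=seed)
        for cond in conditions:
            res = run_condition(cond, train_ds, val_ds, test_ds, tc_run,
                                base_cfg)
            rows.append({k: res[k] for k in
                         ("condition", "seed", "precision", "recall", "f1",
                          "accuracy")})
    return pd.DataFrame(rows)


def pairwise_deltas(table: pd.DataFrame, metric: str = "f1") -> pd.DataFrame:
    """Per-condition medians and deltas in percentage points vs each other."""
    med = table.groupby("condition")[metric].median()
    out = []
    for a in med.index:
        for b in med.index:
            if a != b:
                out.append({"condition_a": a, "condition_b": b,
                            f"delta_{metric}": _round2(med[a] - med[b])})
    return pd.DataFrame(out)
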