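"""Dataset plumbing: labelled image/audio pairs, CSV manifests, 6:2:2 split.

The unit of the dataset is a :class:`LabeledPair` — one thermal infrared
image of a sow's hindquarters matched 1:1 with one vocalisation clip and a
binary estrus label (estrus is the positive class, encoded 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

ESTRUS = 1
NON_ESTRUS = 0

_LABEL_MAP = {
    "estrus": ESTRUS, "non_estrus": NON_ESTRUS,
    "1": ESTRUS, "0": NON_ESTRUS, 1: ESTRUS, 0: NON_ESTRUS,
}

MANIFEST_COLUMNS = ("sample_id", "image_path", "audio_path", "label")


class ManifestError(ValueError):
    """Malformed manifest (missing columns, duplicate ids, bad labels)."""


class StratificationError(ValueError):
    """A class has too few samples to appear in every split."""


@dataclass(frozen=True)
class LabeledPair:
    """One thermal image + one audio clip + binary estrus label."""

    sample_id: str
    image_path: Path
    audio_path: Path
    label: int

    def __post_init__(self):
        if self.label not in (ESTRUS, NON_ESTRUS):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class DatasetSplit:
    """Stratified train/val/test partition of a list of pairs."""

    train: list[LabeledPair]
    val: list[LabeledPair]
    test: list[LabeledPair]
    seed: int
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)

    def sizes(self) -> tuple[int, int, int]:
        return len(self.train), len(self.val), len(self.test)

    def ids(self, part: str) -> set[str]:
        return {p.sample_id for p in getattr(self, part)}


def _coerce_label(raw) -> int:
    key = raw.strip() if isinstance(raw, str) else raw
    if key not in _LABEL_MAP:
        raise ManifestError(f"unrecognised label {raw!r}")
    return _LABEL_MAP[key]


def read_manifest(path: str | Path) -> list[LabeledPair]:
    """Read a CSV manifest into LabeledPairs (file order preserved).

    Referenced image/audio files are *not* opened here; unreadable paths
    surface later, when a consumer loads them.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ManifestError(f"duplicate sample_id values: {dupes[:5]}")
    base = Path(path).parent
    pairs = []
    for row in df.itertuples(index=False):
        img = Path(row.image_path)
        aud = Path(row.audio_path)
        pairs.append(LabeledPair(
            sample_id=str(row.sample_id),
            image_path=img if img.is_absolute() else base / img,
            audio_path=aud if aud.is_absolute() else base / aud,
            label=_coerce_label(row.label),
        ))
    return pairs


def write_manifest(pairs: list[LabeledPair], path: str | Path) -> None:
    df = pd.DataFrame(
        [(p.sample_id, str(p.image_path), str(p.audio_path), p.label)
         for p in pairs],
        columns=list(MANIFEST_COLUMNS),
    )
    df.to_csv(path, index=False)


def _allocate(n: int, ratios: tuple[float, float, float]) -> list[int]:
    """Floor each split size, then hand remainders to train, then val."""
    sizes = [int(np.floor(n * r)) for r in ratios]
    rem = n - sum(sizes)
    for i in range(rem):
        sizes[i % 3] += 1
    return sizes


def split_indices(labels, ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified index partition into (train, val, test).

    Sizes are exact per class (floor then remainder to train, then val),
    deterministic given the seed.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    labels = np.asarray(labels, dtype=int)
    if len(labels) < 5:
        raise ValueError("need at least 5 samples to split")
    rng = np.random.default_rng(seed)
    parts: list[list[np.ndarray]] = [[], [], []]
    for label in (NON_ESTRUS, ESTRUS):
        cls_idx = np.flatnonzero(labels == label)
        if len(cls_idx) == 0:
            continue
        sizes = _allocate(len(cls_idx), ratios)
        if min(sizes) < 1:
            raise StratificationError(
                f"class {label} has {len(cls_idx)} samples, too few for 3 splits")
        shuffled = cls_idx[rng.permutation(len(cls_idx))]
        parts[0].append(shuffled[:sizes[0]])
        parts[1].append(shuffled[sizes[0]:sizes[0] + sizes[1]])
        parts[2].append(shuffled[sizes[0] + sizes[1]:])
    return tuple(np.sort(np.concatenate(p)) for p in parts)


def split_dataset(pairs: list[LabeledPair],
                  ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
                  seed: int = 0) -> DatasetSplit:
    """Stratified, seed-deterministic partition into train/val/test.

    960 balanced pairs at 6:2:2 give 576/192/192.
    """
    labels = [p.label for p in pairs]
    tr, va, te = split_indices(labels, ratios, seed)
    return DatasetSplit(train=[pairs[i] for i in tr],
                        val=[pairs[i] for i in va],
                        test=[pairs[i] for i in te],
                        seed=seed, ratios=tuple(ratios))


def write_split(split: DatasetSplit, outdir: str | Path) -> None:
    """Write train/val/test CSV manifests plus a JSON sidecar with the seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for part in ("train", "val", "test"):
        write_manifest(getattr(split, part), outdir / f"{part}.csv")
    (outdir / "split.json").write_text(json.dumps(
        {"seed": split.seed, "ratios": list(split.ratios),
         "sizes": dict(zip(("train", "val", "test"), split.sizes()))},
        indent=2))
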