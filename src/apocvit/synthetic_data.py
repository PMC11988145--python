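"""Synthetic paired thermal-image / vocalisation generator.

The real farm recordings behind this pipeline are not public, so every
stage is exercised on synthetic pairs that emulate their structure:

* images: a smooth warm background with a localised elliptical warm region
  (the vulvar area) whose intensity elevation is higher in estrus samples,
  plus fine-scale "hair/stain" streak artifacts and sensor noise;
* audio: a harmonic vocalisation (estrus calls sit higher, carry more
  harmonics and an 8 Hz amplitude modulation), mixed with 50 Hz mains hum
  and its harmonics, transient high-frequency chirps (bird-like, 6–8 kHz)
  and broadband noise at a controlled SNR.

Generation is fully deterministic given the spec seed: each sample draws
from its own ``SeedSequence([seed, index])`` stream, so
:func:`ground_truth` can re-derive any sample's latent parameters without
touching the files.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from scipy.io import wavfile
from scipy.ndimage import gaussian_filter

from .core_data import LabeledPair, write_manifest, ESTRUS, NON_ESTRUS


@dataclass(frozen=True)
class SyntheticSpec:
    n_pairs: int = 960
    image_size: tuple[int, int] = (96, 96)
    # warm-region intensity elevation on the [0, 1] scale
    delta_estrus: float = 0.35
    delta_non: float = 0.15
    delta_jitter: float = 0.06
    ellipse_axes: tuple[float, float] = (10.0, 14.0)
    center_jitter: float = 5.0
    hair_density: float = 0.004      # streaks per pixel
    hair_amplitude: float = 0.12
    image_noise_sigma: float = 0.03
    #: probability the vulvar region is occluded (tail/dirt): the warm
    #: ellipse is mostly masked and a visible cool blob covers the area,
    #: so the thermal cue is lost but the occlusion itself is detectable
    image_occlusion_prob: float = 0.08
    # audio
    sample_rate: int = 16000
    duration: float = 1.0
    f0_estrus: tuple[float, float] = (250.0, 350.0)
    f0_non: tuple[float, float] = (120.0, 180.0)
    harmonics_estrus: int = 5
    harmonics_non: int = 3
    am_rate_estrus: float = 8.0      # Hz amplitude modulation, estrus only
    #: probability that a clip's vocalisation comes from the other class's
    #: call repertoire (vocal patterns overlap between states, which is why
    #: audio alone is the weaker modality)
    call_overlap_prob: float = 0.25
    hum_freq: float = 50.0
    hum_level: float = 0.4           # amplitude relative to unit-RMS call
    chirp_band: tuple[float, float] = (6000.0, 7800.0)
    chirp_level: float = 0.3
    noise_snr_db: float = -10.0      # broadband noise SNR re the call (mean)
    noise_snr_jitter_db: float = 15.0  # per-clip SNR drawn U(mean±jitter)
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs % 2:
            raise ValueError("n_pairs must be even (balanced classes)")
        if self.delta_estrus < self.delta_non:
            raise ValueError("delta_estrus must be >= delta_non")
        nyq = self.sample_rate / 2
        top = max(self.chirp_band[1], self.f0_estrus[1] * self.harmonics_estrus)
        if top >= nyq and self.chirp_band[1] >= nyq:
            raise ValueError("chirp band exceeds Nyquist")

    def null(self) -> "SyntheticSpec":
        """Same marginals for both classes: no separable signal at all."""
        return replace(self,
                       delta_non=self.delta_estrus,
                       f0_non=self.f0_estrus,
                       harmonics_non=self.harmonics_estrus,
                       call_overlap_prob=0.5)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))


def _sample_id(index: int, label: int) -> str:
    return f"s{index:04d}_{'estrus' if label else 'nonestrus'}"


def _label_of(index: int) -> int:
    """Alternate classes so any prefix of the manifest stays balanced."""
    return ESTRUS if index % 2 == 0 else NON_ESTRUS


def _latents(spec: SyntheticSpec, index: int) -> dict:
    """Latent generative parameters for sample ``index`` (deterministic)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, index]))
    label = _label_of(index)
    delta = spec.delta_estrus if label == ESTRUS else spec.delta_non
    call_class = label
    if rng.uniform() < spec.call_overlap_prob:
        call_class = 1 - label
    if call_class == ESTRUS:
        f0 = rng.uniform(*spec.f0_estrus)
        harmonics = spec.harmonics_estrus
        am_rate = spec.am_rate_estrus
    else:
        f0 = rng.uniform(*spec.f0_non)
        harmonics = spec.harmonics_non
        am_rate = 0.0
    delta = delta + rng.uniform(-spec.delta_jitter, spec.delta_jitter)
    occluded = bool(rng.uniform() < spec.image_occlusion_prob)
    if occluded:
        delta *= rng.uniform(0.2, 0.5)
    h, w = spec.image_size
    center = (h * 0.55 + rng.uniform(-spec.center_jitter, spec.center_jitter),
              w * 0.5 + rng.uniform(-spec.center_jitter, spec.center_jitter))
    return {
        "index": index,
        "label": label,
        "call_class": int(call_class),
        "occluded": occluded,
        "elevation": float(delta),
        "center": (float(center[0]), float(center[1])),
        "f0": float(f0),
        "harmonics": harmonics,
        "am_rate": float(am_rate),
        "snr_db": float(spec.noise_snr_db + rng.uniform(
            -spec.noise_snr_jitter_db, spec.noise_snr_jitter_db)),
        "stream": rng,   # consumed by the renderers, in a fixed order
    }


def render_image(spec: SyntheticSpec, lat: dict) -> np.ndarray:
    """Float image in [0, 1]: background + warm ellipse + hair + noise."""
    rng: np.random.Generator = lat["stream"]
    h, w = spec.image_size
    yy, xx = np.mgrid[0:h, 0:w]
    background = 0.30 + 0.10 * (yy / h)                       # body gradient
    texture = gaussian_filter(rng.normal(0, 1.0, (h, w)), 6.0)
    background = background + 0.04 * texture / max(texture.std(), 1e-12)
    cy, cx = lat["center"]
    ay, ax = spec.ellipse_axes
    d2 = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
    warm = lat["elevation"] * np.exp(-0.5 * d2 * 2.0)         # soft ellipse
    img = background + warm
    if lat["occluded"]:
        # cool occluder (tail/dirt) across the vulvar area: kills the
        # thermal cue but is itself conspicuous
        ang = rng.uniform(0, np.pi)
        u = (yy - cy) * np.cos(ang) + (xx - cx) * np.sin(ang)
        v = -(yy - cy) * np.sin(ang) + (xx - cx) * np.cos(ang)
        blob = np.exp(-0.5 * ((u / (2.0 * ay)) ** 2 + (v / (0.45 * ax)) ** 2))
        img -= rng.uniform(0.10, 0.18) * blob
    n_hairs = rng.poisson(spec.hair_density * h * w)
    for _ in range(n_hairs):
        y0, x0 = rng.uniform(0, h), rng.uniform(0, w)
        angle = rng.uniform(0, np.pi)
        length = rng.uniform(3, 10)
        amp = rng.normal(0, spec.hair_amplitude)
        steps = int(length)
        ys = (y0 + np.cos(angle) * np.arange(steps)).astype(int) % h
        xs = (x0 + np.sin(angle) * np.arange(steps)).astype(int) % w
        img[ys, xs] += amp
    img += rng.normal(0, spec.image_noise_sigma, (h, w))
    return np.clip(img, 0.0, 1.0)


def render_audio(spec: SyntheticSpec, lat: dict) -> np.ndarray:
    """Float waveform in [-1, 1]: call + hum + chirps + broadband noise."""
    rng: np.random.Generator = lat["stream"]
    n = spec.n_samples
    t = np.arange(n) / spec.sample_rate
    call = np.zeros(n)
    for k in range(1, lat["harmonics"] + 1):
        phase = rng.uniform(0, 2 * np.pi)
        call += (0.8 / k) * np.sin(2 * np.pi * k * lat["f0"] * t + phase)
    if lat["am_rate"] > 0:
        call *= 0.5 * (1.0 + 0.9 * np.sin(2 * np.pi * lat["am_rate"] * t))
    call /= max(np.sqrt(np.mean(call ** 2)), 1e-12)           # unit RMS
    hum = np.zeros(n)
    for k in (1, 2, 3):
        hum += (spec.hum_level / k) * np.sin(
            2 * np.pi * k * spec.hum_freq * t + rng.uniform(0, 2 * np.pi))
    chirps = np.zeros(n)
    for _ in range(rng.integers(2, 5)):
        fc = rng.uniform(*spec.chirp_band)
        t0 = rng.uniform(0.05, spec.duration - 0.1)
        width = rng.uniform(0.005, 0.02)
        env = np.exp(-0.5 * ((t - t0) / width) ** 2)
        chirps += spec.chirp_level * env * np.sin(2 * np.pi * fc * t)
    noise_rms = 10.0 ** (-lat["snr_db"] / 20.0)               # call has RMS 1
    noise = rng.normal(0, noise_rms, n)
    x = call + hum + chirps + noise
    return x / max(np.abs(x).max(), 1e-12) * 0.9


def ground_truth(spec: SyntheticSpec, sample_id: str) -> dict:
    """Latent parameters (elevation, f0, SNR, ...) behind a generated sample."""
    try:
        index = int(sample_id[1:5])
    except (ValueError, IndexError):
        raise KeyError(f"malformed sample_id {sample_id!r}")
    if not (0 <= index < spec.n_pairs) or _sample_id(index, _label_of(index)) != sample_id:
        raise KeyError(f"unknown sample_id {sample_id!r}")
    lat = _latents(spec, index)
    lat.pop("stream")
    return lat


def generate_arrays(spec: SyntheticSpec) -> dict:
    """In-memory dataset: images (n,H,W), audio (n,L), labels, ids, latents."""
    images, audio, labels, ids, latents = [], [], [], [], []
    for i in range(spec.n_pairs):
        lat = _latents(spec, i)
        images.append(render_image(spec, lat))
        audio.append(render_audio(spec, lat))
        labels.append(lat["label"])
        ids.append(_sample_id(i, lat["label"]))
        lat.pop("stream")
        latents.append(lat)
    return {
        "images": np.stack(images),
        "audio": np.stack(audio),
        "labels": np.array(labels, dtype=int),
        "sample_ids": ids,
        "latents": latents,
    }


def generate(spec: SyntheticSpec, outdir: str | Path) -> list[LabeledPair]:
    """Write PNG images, WAV clips, a CSV manifest and the spec as YAML."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "audio").mkdir(parents=True, exist_ok=True)
    pairs = []
    for i in range(spec.n_pairs):
        lat = _latents(spec, i)
        sid = _sample_id(i, lat["label"])
        img = render_image(spec, lat)
        wav = render_audio(spec, lat)
        img_path = outdir / "images" / f"{sid}.png"
        wav_path = outdir / "audio" / f"{sid}.wav"
        Image.fromarray((img * 255).round().astype(np.uint8)).save(img_path)
        wavfile.write(wav_path, spec.sample_rate,
                      (np.clip(wav, -1, 1) * 32767).round().astype(np.int16))
        pairs.append(LabeledPair(sample_id=sid, image_path=img_path,
                                 audio_path=wav_path, label=lat["label"]))
    write_manifest(pairs, outdir / "manifest.csv")
    with open(outdir / "spec.yaml", "w") as fh:
        yaml.safe_dump(asdict(spec), fh)
    return pairs


# ---------------------------------------------------------------------
# hand-crafted oracle features (generator calibration / sanity floor)
# ---------------------------------------------------------------------

def oracle_image_feature(img: np.ndarray) -> float:
    """Warm-region cue: mean of the hottest 8% of pixels above the image
    median (the warm ellipse dominates the upper tail)."""
    flat = np.sort(img.ravel())
    top = flat[-max(1, int(0.08 * flat.size)):]
    return float(top.mean() - np.median(flat))


def oracle_audio_feature(wave: np.ndarray, sample_rate: int,
                         split_hz: float = 215.0) -> float:
    """Call-band cue: power above/below the boundary between the two
    fundamental-frequency bands, as a log ratio."""
    spectrum = np.abs(np.fft.rfft(wave)) ** 2
    freqs = np.fft.rfftfreq(len(wave), 1.0 / sample_rate)
    hi = spectrum[(freqs >= split_hz) & (freqs <= 2000.0)].sum()
    lo = spectrum[(freqs >= 80.0) & (freqs < split_hz)].sum()
    return float(np.log10((hi + 1e-12) / (lo + 1e-12)))


def oracle_features(images: np.ndarray, audio: np.ndarray,
                    sample_rate: int) -> np.ndarray:
    """(n, 2) matrix of the two hand-crafted features."""
    return np.column_stack([
        [oracle_image_feature(im) for im in images],
        [oracle_audio_feature(wv, sample_rate) for wv in audio],
    ])
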