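"""Vocalisation denoising in the frequency domain.

Farm recordings mix pig vocalisations with mains/fan hum, bird chirps,
dripping water and broadband noise. The clean-up is purely spectral:

    FFT -> multiply each bin by the Chebyshev Type-I band-pass magnitude
    response |H(f)| -> inverse FFT.

The magnitude response comes from the analog low-pass prototype

    |H(jω)| = G / sqrt(1 + ε² T_N²(ω/ω_p)),   ε = sqrt(10^(ripple_dB/10) − 1)

mapped to a band-pass via the standard substitution
ω_lp = |ω² − ω₀²| / (B·ω) with ω₀² = ω_lo·ω_hi and B = ω_hi − ω_lo.
Applying |H| bin-wise is zero-phase: the filtered waveform is not delayed.
A conventional time-domain IIR mode (scipy cheby1 + filtfilt) is available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.io import wavfile


@dataclass
class AudioClip:
    """Mono waveform with its sample rate."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim == 2:  # stereo -> mono by channel averaging
            self.samples = self.samples.mean(axis=1)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples ** 2)))


@dataclass
class ChebyshevBandpassSpec:
    """Chebyshev Type-I band-pass filter specification.

    order: polynomial order N of the low-pass prototype.
    ripple_db: passband ripple in dB; the ripple factor is
        ε = sqrt(10^(ripple_db/10) − 1).
    band: (f_lo, f_hi) passband edges in Hz.
    gain: peak passband gain G.
    """

    order: int = 4
    ripple_db: float = 0.5
    band: tuple[float, float] = (100.0, 4000.0)
    gain: float = 1.0

    def __post_init__(self):
        f_lo, f_hi = self.band
        if not (0 < f_lo < f_hi):
            raise ValueError("need 0 < f_lo < f_hi")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.ripple_db <= 0:
            raise ValueError("ripple_db must be positive")

    @property
    def epsilon(self) -> float:
        return float(np.sqrt(10.0 ** (self.ripple_db / 10.0) - 1.0))

    def validate_for_rate(self, sample_rate: int) -> None:
        if self.band[1] >= sample_rate / 2:
            raise ValueError(
                f"f_hi={self.band[1]} Hz is at/above Nyquist for "
                f"{sample_rate} Hz")


def load_wav(path: str | Path) -> AudioClip:
    """Read a WAV file (PCM int or float) as a mono float clip in [-1, 1]."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    return AudioClip(data.astype(np.float64), rate)


def save_wav(clip: AudioClip, path: str | Path, dtype: str = "int16") -> None:
    x = np.clip(clip.samples, -1.0, 1.0)
    if dtype == "int16":
        wavfile.write(path, clip.sample_rate,
                      (x * 32767.0).round().astype(np.int16))
    elif dtype == "float32":
        wavfile.write(path, clip.sample_rate, x.astype(np.float32))
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")


def fft(clip: AudioClip) -> np.ndarray:
    """Full-length DFT X(f) = Σ x(n)·exp(−j2πfn/N)."""
    if len(clip.samples) == 0:
        raise ValueError("empty signal")
    return np.fft.fft(clip.samples)


def ifft(bins: np.ndarray, sample_rate: int) -> AudioClip:
    """Inverse DFT back to a real waveform (imaginary residue discarded)."""
    return AudioClip(np.real(np.fft.ifft(bins)), sample_rate)


def _cheb_poly(order: int, x: np.ndarray) -> np.ndarray:
    """Chebyshev polynomial T_N evaluated for any real argument.

    cos(N arccos x) inside [-1, 1], cosh(N arccosh |x|) outside (even/odd
    symmetry handled by sign).
    """
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    inside = np.abs(x) <= 1.0
    out[inside] = np.cos(order * np.arccos(x[inside]))
    xo = np.abs(x[~inside])
    sign = np.where((x[~inside] < 0) & (order % 2 == 1), -1.0, 1.0)
    out[~inside] = sign * np.cosh(order * np.arccosh(xo))
    return out


def cheby1_magnitude(spec: ChebyshevBandpassSpec, f) -> np.ndarray | float:
    """|H(f)| of the band-pass realisation of the Type-I prototype.

    Returns G/sqrt(1+ε²) exactly at the passband edges and tends to 0 at
    DC and infinity. Accepts a scalar or an array of frequencies in Hz.
    """
    f = np.asarray(f, dtype=np.float64)
    scalar = f.ndim == 0
    f = np.atleast_1d(f)
    w = 2.0 * np.pi * f
    w_lo = 2.0 * np.pi * spec.band[0]
    w_hi = 2.0 * np.pi * spec.band[1]
    w0_sq = w_lo * w_hi
    bw = w_hi - w_lo
    with np.errstate(divide="ignore", invalid="ignore"):
        w_lp = np.abs(w * w - w0_sq) / (bw * w)
    w_lp[w == 0] = np.inf
    eps2 = spec.epsilon ** 2
    t = np.where(np.isinf(w_lp), np.inf, _cheb_poly(spec.order,
                                                    np.where(np.isinf(w_lp), 1.0, w_lp)))
    with np.errstate(over="ignore"):
        mag = spec.gain / np.sqrt(1.0 + eps2 * t * t)
    mag[np.isinf(w_lp)] = 0.0
    return float(mag[0]) if scalar else mag


def bandpass_filter(clip: AudioClip, spec: ChebyshevBandpassSpec,
                    mode: str = "spectral") -> AudioClip:
    """Apply the band-pass filter.

    ``spectral`` (default): FFT -> bin-wise multiply by |H(f)| -> inverse
    FFT. Zero phase, energy never increases for G=1.
    ``iir``: conventional time-domain Chebyshev-I filtering via scipy's
    cheby1 design with filtfilt (also zero-phase, squared magnitude).
    """
    spec.validate_for_rate(clip.sample_rate)
    if mode == "iir":
        sos = signal.cheby1(spec.order, spec.ripple_db,
                            spec.band, btype="bandpass",
                            fs=clip.sample_rate, output="sos")
        return AudioClip(spec.gain * signal.sosfiltfilt(sos, clip.samples),
                         clip.sample_rate)
    if mode != "spectral":
        raise ValueError(f"unknown mode {mode!r}")
    bins = fft(clip)
    n = len(bins)
    freqs = np.abs(np.fft.fftfreq(n, d=1.0 / clip.sample_rate))
    response = cheby1_magnitude(spec, freqs)
    return ifft(bins * response, clip.sample_rate)


def denoise_audio(clip: AudioClip,
                  spec: ChebyshevBandpassSpec | None = None) -> AudioClip:
    """FFT -> Chebyshev band-pass magnitude -> inverse FFT."""
    return bandpass_filter(clip, spec or ChebyshevBandpassSpec())


def band_power_fraction(clip: AudioClip, band: tuple[float, float]) -> float:
    """Fraction of total spectral power inside ``band`` (Hz)."""
    bins = np.fft.rfft(clip.samples)
    freqs = np.fft.rfftfreq(len(clip.samples), d=1.0 / clip.sample_rate)
    power = np.abs(bins) ** 2
    total = power.sum()
    if total == 0:
        return 0.0
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(power[sel].sum() / total)
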