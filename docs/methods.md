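# Methods

## Problem and model

The task is binary classification of sow reproductive state (estrus vs
non-estrus) from a paired observation: one thermal infrared image of the
hindquarters and one short audio clip recorded at the pen. The two
physiological cues are complementary — vulvar-region warming shows in
the image; vocalisation characteristics (higher fundamental, richer
harmonics, rhythmic amplitude modulation) show in the audio — and each
is unreliable on its own: thermal contrast is diluted by hair, stains
and sensor noise, while pen audio is contaminated by hum, transient
chirps and broadband noise, and the vocal repertoires of the two states
overlap. The model therefore (a) denoises each modality with classical
signal processing, (b) encodes each with a dedicated neural branch,
(c) fuses the two pooled feature vectors with a learned scalar gate, and
(d) classifies the fused representation with a DenseNet-SE head.

### Image path

Pixel intensities are min–max normalised to [0, 1], z-scored per image
(population standard deviation), then wavelet-denoised: a multi-level
2-D DWT, hard thresholding of every detail band (coefficients with
magnitude below λ are zeroed; survivors are kept unchanged; the coarsest
approximation band is never touched), and the inverse DWT. Defaults:
Daubechies-4, two levels, and the universal threshold
λ = σ̂·sqrt(2·ln n) with σ̂ = median(|finest diagonal band|)/0.6745.
The DWT uses the `periodization` signal extension so the transform is
orthonormal: coefficient energy equals pixel energy (relative error
below 1e-6 in tests) and the round trip is exact to 1e-8 at every size —
these identities anchor the energy-bookkeeping tests, which is why
periodization is the default rather than symmetric extension (available
via `DenoiseConfig.dwt_mode`). Soft thresholding sits behind a flag,
off by default. Whether standardisation should be global or per-image is
an open choice; per-image is implemented, matching the per-image
normalisation step.

### Audio path

Stereo input is averaged to mono. Denoising is purely spectral: the full
FFT, bin-wise multiplication by the magnitude response of a Chebyshev
Type-I band-pass filter, and the inverse FFT. The magnitude comes from
the analog prototype |H(jω)| = G/√(1+ε²T²_N(ω/ω_p)) under the standard
low-pass→band-pass mapping ω_lp = |ω²−ω₀²|/(B·ω). Applying |H| in the
frequency domain is zero-phase (verified by a zero cross-correlation
lag) and never amplifies (|H| ≤ G). Defaults: order 4, ripple 0.5 dB
(ε ≈ 0.349), passband 100–4000 Hz — wide enough for grunt fundamentals
and scream harmonics, excluding mains hum and high-frequency bird
chirps; these values are package defaults, not measurements from any
particular farm. A conventional time-domain IIR mode
(`bandpass_filter(..., mode="iir")`, scipy design + `filtfilt`) is
provided; the closed-form magnitude is itself cross-checked against
scipy's analog design in the tests.

### Feature extractors

*Image*: a ViT-style encoder. The image is cut into non-overlapping
patches (kernel = stride = patch size, implemented as a reshape + linear
map, which is the same operation as the conventional convolutional patch
embedding), a learned positional table is added, and the tokens pass
through pre-norm transformer layers — LayerNorm, multi-head
self-attention softmax(QKᵀ/√d_k)·V, residual, LayerNorm,
FFN(x)=ReLU(xW₁+b₁)W₂+b₂, residual — followed by a final LayerNorm and
token mean-pooling (no CLS token). Pre-norm is used for small-scale
training stability.

*Audio*: three 1-D convolution → ReLU → average-pool stages; the third
convolution is dilated (default rate 2), widening its receptive field at
constant parameter count. Convolutions use circular padding, which makes
the extractor exactly invariant to circular time shifts that are
multiples of the cumulative pooling stride — a tested invariant. A
global average over time and a linear map produce the feature vector.
The input representation is the filtered waveform itself (not a
spectrogram): the denoising chain outputs a waveform, and the
first-layer filters can learn band detectors directly.

### Fusion

With X the pooled image feature and Y the audio feature, the gate is

    H⁰ = ReLU(W_in·[X,Y] + b_in),  Hᵏ = ReLU(W_k·Hᵏ⁻¹ + b_k),
    A  = sigmoid(W_out·Hᵏ + b_out) ∈ (0, 1),

and the fused vector is the convex combination A·proj_img(X) +
(1−A)·proj_aud(Y), where the projections map both modalities to a common
dimension. A is a *scalar per sample* by default, so the fixed-weight
baselines (1/0, 0.7/0.3, 0.5/0.5, 0.3/0.7, 0/1) are exact special cases
of the same wiring — the bitwise equivalence is tested. A per-dimension
vector gate exists behind `vector_gate=True`.

Two gate design choices matter for training behaviour. First, the gate
reads *detached* (stop-gradient) copies of X and Y: it routes between
modalities without back-propagating its own objective into the encoders,
so the shared weights receive exactly the mixture gradients — adaptive
fusion is then the fixed mixture plus a loss-driven refinement of the
weighting, rather than a differently-regularised model. Second, the gate
head W_out is zero-initialised so A starts exactly at 0.5: adaptive
fusion begins bit-for-bit as the balanced fixed mixture and departs from
it only where the gradient favours gating. Together these make the
adaptive-versus-fixed comparison in the ablation an apples-to-apples one.
MLP depth 2 and hidden width 128 (64 in the reduced configuration) are
defaults; nothing in the architecture pins them.

### Classifier

The fused vector is reshaped bijectively into a small C₀×h₀×w₀ map
(default 4×8×8 from 256 dims) — an information-preserving adapter chosen
over a 1-D DenseNet variant to keep the conventional conv/pool layout.
A stem convolution is followed by three dense blocks: each internal
layer consumes the concatenation of the block input and all previous
layer outputs, so a block with L layers and growth g adds L·g channels
(channel bookkeeping is asserted at every boundary). After each block a
Squeeze-and-Excitation gate — global average pool per channel, bottleneck
FC (reduction r, clamped to keep at least one unit), ReLU, restoring FC,
sigmoid — rescales the channels; gates are strictly inside (0,1), never
flip signs, and forcing them to exactly 1 (saturating the bias)
reproduces the plain DenseNet bit for bit, which is the SE-ablation
wiring test. Average pooling (stride 2) downsamples between blocks;
global average pooling and a fully connected layer give 2 logits trained
with softmax cross-entropy (estrus = class 1).

## Training

Adam (lr 0.001), batch size 16, with a reduce-on-plateau schedule: the
validation loss is monitored each epoch and the learning rate is
multiplied by 0.1 after 5 epochs without a new best ("drop period 5"
read as plateau patience, since the procedure is validation-monitored;
a fixed-step decay mode also exists). The best-validation-loss weights
are retained. Everything is seeded: weight init, batch order, and the
synthetic data itself, so equal seeds give identical loss histories.

## Metrics

P = 100·TP/(TP+FP), R = 100·TP/(TP+FN), F1 = 2PR/(P+R), reported
rounded half-up to two decimals with raw values retained; degenerate
denominators yield 0 with a flag. Estrus is the positive class.

## Synthetic data generator

Each sample draws from its own `SeedSequence([seed, index])` stream, so
any sample's latent parameters can be re-derived without reading files,
and generation is byte-reproducible.

*Images* (96×96, [0,1]): a smooth background (vertical gradient +
Gaussian-smoothed texture), a soft elliptical warm region near the
vulvar position whose elevation is Δ_estrus = 0.35 vs Δ_non = 0.15
(±0.06 jitter, centre jitter ±5 px), short hair/stain streaks
(amplitude ~N(0, 0.12)) and sensor noise (σ = 0.03). With probability
0.08 the vulvar region is *occluded* (a tail or dirt): the warm
elevation is scaled to 20–50% and a conspicuous cool elongated blob is
drawn over the area — the thermal cue is largely lost but the occlusion
itself is visible, so a cross-modal gate can learn to discount the
image for exactly those samples.

*Audio* (1 s at 16 kHz): a harmonic call — estrus: fundamental
U(250, 350) Hz, 5 harmonics, 8 Hz amplitude modulation; non-estrus:
U(120, 180) Hz, 3 harmonics, no AM — normalised to unit RMS, plus 50 Hz
hum with harmonics, 2–4 transient 6–7.8 kHz chirps, and white noise at a
per-clip SNR drawn U(−25, +5) dB. With probability 0.25 the clip's call
is drawn from the *other* class's repertoire: vocal patterns genuinely
overlap between states, which is what makes audio the weaker modality.
The three reliability degraders (wide audio SNR spread, call overlap,
image occlusion) were calibrated once against the logistic oracle below
so that the default task is learnable but not trivial (combined oracle
accuracy ≈ 0.9, image stronger than audio) and the two modalities are
*complementarily* unreliable — each modality fails on a different,
detectable subset of samples, which is the regime where adaptive
weighting has value a fixed weight cannot express — and then frozen.

What the generator does *not* emulate: radiometric temperature
calibration, animal identity (no per-animal grouping, so no
identity-leakage control), posture/occlusion variation, reverberation,
or realistic call segmentation. Passing tests therefore demonstrate that
the pipeline's machinery works and that fusion exploits complementary,
unequally reliable modalities — not that any particular accuracy will
transfer to real farm data.

*Oracle features*: mean of the hottest 8% of pixels minus the image
median (warm-region cue) and the log power ratio above/below 215 Hz
within 80–2000 Hz (call-band cue). A standardised logistic regression on
these two features is the sanity floor and the null-calibration
instrument.

## Desk-scale study conditions

The stochastic experiments run a reduced configuration sized for a
single CPU (the package's own choice of problem size): 400 balanced
pairs split 6:2:2; images resized to 32×32 (patch 4 — 64 tokens, fine
enough to resolve the small warm ellipse reliably — embed 64, depth 2,
2 heads); audio band-passed then resampled to 2 kHz (2000 samples;
channels 8/16/32, pools 4/4/4, dilation 2); fused dimension 64 reshaped
to 4×4×4; 12 epochs (with best-validation checkpointing, results are
insensitive to training longer). The fusion ablation trains image-only, audio-only,
fixed 0.5/0.5 and adaptive fusion over ten seeds with identical data
order and identical initial encoder weights per seed, so per-seed deltas
are attributable to the fusion mechanism alone. The null calibration
regenerates the dataset with both class distributions equalised
(Δ equal, same call repertoire, overlap probability 0.5) and checks that
the oracle classifier's test accuracy is 50% within Monte-Carlo error
(three empirical standard errors over ten seeds).

## Numerical choices

- float64 throughout the autodiff engine; softmax rows sum to 1 within
  1e-9 and the sigmoid saturates to exactly 1.0 for arguments ≥ ~40.
- Convolution outputs are materialised C-contiguous so that reductions
  downstream are layout-independent — this is what makes the
  "forced SE gates ≡ plain DenseNet" and "adaptive ≡ fixed" identities
  hold bitwise rather than to rounding error.
- Reported percentages round half-up (decimal arithmetic, not banker's
  rounding) to match conventional table formatting.
- Degenerate inputs: constant images normalise to zero with a warning;
  zero-variance images refuse to standardise; empty signals refuse the
  FFT; a class too small to appear in all three splits raises.

## Known limitations

- The NumPy engine is single-threaded-friendly but slow; the full-size
  defaults (224×224 ViT, 16 kHz audio) are usable for inference-scale
  experiments only.
- The scalar gate weighs whole samples, not tokens or time frames; no
  token-level cross-modal attention.
- No pretrained weights anywhere; results on real data would require the
  original recordings, which are not public.
- Checkpoints are JSON (portable, diffable) and are not size-optimised.
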