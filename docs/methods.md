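# Methods

This note documents the models, the synthetic study conditions, and the
numerical and design choices behind `beatbench`, in the spirit of a
model-description appendix. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Beat model and preprocessing

A *beat* is one cardiac cycle as a fixed-length amplitude vector. The
working length is 256: segmentation cuts 280 samples (at 360 Hz) around
each R peak — 140 before, 140 after, half-open windows, 0-based indices
— and band-limited Fourier resampling maps 280 → 256. The symmetric
window centres the QRS; windows that leave the record are dropped rather
than padded, so no samples are fabricated. Fourier resampling is linear
and preserves constants; a polyphase alternative is available behind a
flag and differs only in band-edge behaviour.

QRS detection is the Pan-Tompkins pipeline: 5–15 Hz band-pass,
five-point derivative, squaring, 150 ms moving-window integration,
adaptive dual thresholds with an eight-interval RR history, search-back
at 1.66× the average RR, and a 200 ms refractory period. The band-pass
is applied forward-backward (zero phase), which removes the classic
filter delay; each integration peak is then mapped to the R apex by a
local maximum search of the filtered signal inside one integration
window. On the synthetic records used in tests (20–30 beats, amplitude
noise s.d. 0.05, RR jitter 20–30 ms) recall and precision are ≥ 0.9
within a ±50 ms matching window.

Normalization is per-beat min-max onto [−1, 1] by default. Every
generator ends in a tanh, so real and generated beats must share that
range; per-beat scaling also makes beats gain-free. A global min-max
mode preserves relative amplitudes across a set when that matters.
Per-beat scaling of a constant beat is undefined and raises.

## Synthetic study conditions

The fixture generator emulates segmented normal beats as a sum of five
Gaussian waves on the unit interval, with per-draw jitter and additive
noise, then per-beat normalization:

s(j) = Σ_w ã_w exp(−(j/L − μ̃_w)² / 2σ_w²) + ε_j,  w ∈ {P, Q, R, S, T}

The frozen preset `normal_v1` uses centres μ = (0.18, 0.42, 0.50, 0.58,
0.78), amplitudes a = (0.15, −0.12, 1.0, −0.22, 0.30), widths σ =
(0.035, 0.012, 0.016, 0.012, 0.055). Amplitude jitter is multiplicative
with s.d. 5% of each wave's nominal amplitude. Centre jitter is additive
with s.d. 0.008 of the beat length (≈ 2 samples): segmentation anchors
beats at the R apex, so residual landmark wobble of a couple of samples
is what real segmented sets show. Noise s.d. is 0.02. Records place
these beats at jittered RR intervals with a 0.33 Hz sinusoidal baseline
wander, and carry ground-truth R positions and annotations.

The second class, `lbbb_v1`, carries the lead-I signature of a left
bundle branch block: R width tripled, S deepened to −0.5 and widened to
0.03, T inverted to −0.3. A deepened-S-only variant proved inadequate —
under 5% amplitude jitter and per-beat normalization its within-class
DTW spread exceeded its distance to the normal class — so the fuller
(and clinically more faithful) morphology is used; the test suite checks
that between-class mean DTW exceeds both within-class means.

What the generator does *not* emulate: heart-rate-dependent interval
scaling, respiratory amplitude modulation, electrode artefacts, ectopy,
or any within-record nonstationarity. Passing tests therefore show that
the pipeline's logic is correct under clean, unimodal, well-separated
morphologies — not that any model reaches a particular quality on real
recordings.

Every fixture is a pure function of (parameters, n, seed); per-beat
seeds derive from the master seed by a counter scheme so element i is
reproducible regardless of draw order.

## The five generative models

All generators map a standard-normal latent vector to 256 samples
through a terminal tanh. Training uses Adam (learning rate 2·10⁻⁴,
β₁ = 0.5, β₂ = 0.999), batch size 9 with the last incomplete batch
dropped, 30 epochs, weights initialized N(0, 0.02) (batch-norm scale
N(1, 0.02)), and 10 beats sampled after every epoch.

- **classic** — fully connected: 100→128→256→512→1024→256 with
  leaky-ReLU(0.2) and batch norm; discriminator 256→512→256→1 with a
  sigmoid. Binary cross-entropy minimax, non-saturating generator loss.
- **dcdc** — the latent is reshaped to 100 channels × length 1 and
  upsampled by five transposed convolutions (512, 256, 128, 64, 1
  channels), then a final FC + tanh; convolutional discriminator
  (64→128→256→512→1 channels) with FC + sigmoid readout.
- **bilstm_dc** — a 2-layer bidirectional LSTM (hidden 1000) receives
  the latent as a single time step; the concatenated final hidden states
  (2000) feed FC(2000, 256) + tanh. Same convolutional discriminator.
  With one time step the recurrent weights' contribution from the zero
  initial state vanishes, but they remain trainable parameters of the
  stated architecture.
- **vaegan** — an FC encoder with a 10-dimensional reparameterized
  bottleneck (z = μ + ε·exp(logvar/2)) and an FC decoder. The
  discriminator takes the 10-d *code*, so the adversarial game matches
  the encoded posterior to the prior (adversarial-autoencoder reading —
  the only one consistent with a first discriminator layer of width 10).
  Encoder/decoder minimize λ_rec·L1(decoded, real) + λ_kl·KL + λ_adv·BCE
  with frozen defaults λ_rec = 10, λ_adv = 1, λ_kl = 1; sampling feeds
  prior draws to the decoder.
- **wgan** — deep-convolutional critic (64…2048 channels, no terminal
  sigmoid) and generator; critic loss mean D(fake) − mean D(real),
  generator loss −mean D(fake), weights clipped to ±0.01 after every
  critic step, 5 critic steps per generator step. The optimizer stays
  Adam for uniformity with the global configuration (the original
  weight-clipping recipe used RMSProp; documented as a deviation).

Convolution geometry, where only channel counts are prescribed: kernel
4, stride 2, padding 1 throughout, except the WGAN generator's first two
transposed convolutions use stride 4 (kernel 4, padding 0) so that six
upsampling layers reach exactly 256 from a length-1 seed. Flatten
dimensions ahead of final FC layers are computed from the actual
architecture rather than hard-coded (a listed "FC(13, 1)" is treated as
an instance of this dynamic sizing, since no stated kernel choice
produces length 13 from 256). No label smoothing, minibatch
discrimination, or gradient penalty anywhere.

The engine underneath (`beatbench.nn`) is a deliberately small
reverse-mode tape over float64 numpy arrays — dynamic graph, im2col
convolutions, broadcasting-aware backward — checked against central
finite differences in the test suite. Determinism on one platform is
bit-level given one master seed; seeds fan out to named substreams
(data, init, train, sampling, eval) by a CRC-based counter scheme.

## Evaluation framework

Scores per distance function: s1 (cross-set mean over uniform
without-replacement subsamples, default 300/300 — with full portions it
is the deterministic double mean, and the sampled pool of a default
training run is exactly 300 beats), s2 (mean to template), s3 (best
beat, ties to the lowest index), threshold η = (s2 + s3)/2 (a factor
mode a·s3 is available), s4 = percentage of beats with distance ≤ η
(inclusive, so the best beat is always accepted and s4 ≥ 100/N_G).
DTW local cost is the absolute difference (the scalar Euclidean case);
no warping window, symmetric steps. The Fréchet implementation is the
discrete variant — the coupling definition over sampled points — which
the tests verify to be a metric; DTW and Euclidean are not.

Templates: the statistically-averaged beat is computed on normalized
beats without landmark registration, and is therefore smeared where
landmarks jitter — accepted, as the best per-time-step statistical
summary. The "expert eye" selection has no algorithm, so its
deterministic proxy is the DTW-medoid of a seeded 100-beat subsample;
an explicit index mode lets a human override. Which template feeds the
scoring is recorded in report metadata (default: medoid). Methods 2–4
score the final sampled pool by default and can be pointed at the
cross-epoch pool; subjective visual inspection is supported only by
exporting galleries, never as a computed score.

## Augmentation experiment

Two single-class pools (normal and the wide-QRS class) are split into a
held-out test set and three training scenarios: balanced real,
imbalanced (minority subsampled), and the imbalanced set topped back up
with synthetic minority beats. The test split is drawn first and is
bit-identical across scenarios. Full-scale sizes mirror the two-class
benchmark (6457/6455 balanced, 500/6460 imbalanced, 6454/6458
rebalanced, 1609/1607 test); the default *scaled* preset (500/500,
50/500, 500/500, 150/150) keeps the experiment in CPU seconds, and the
methods' logic does not depend on the absolute counts.

The classifier is a 1-D residual network — stacked blocks of two
kernel-3 convolutions with identity shortcuts F(x) + x — trained from
scratch (no ImageNet-style pretraining: irrelevant to the experiment's
logic and not reproducible at desk scale; a deviation by design) with
Adam at 10⁻³, batch 32, softmax cross-entropy. The scaled preset is 10
conv layers with 8/16 channels and 10 epochs — enough steps to escape
the all-majority collapse on these conditions (at 6 epochs it sometimes
does not, which is the imbalance pathology itself); the 34-layer
configuration (3/4/6/3 blocks, 64–512 channels) is available behind the
`resnet34` preset. Synthetic minority beats come from the fixture
generator by default, isolating the experiment from GAN training
stochasticity; a trained generator can supply them instead.

The reported comparison is per-class precision/recall/F1/support,
accuracy, macro and weighted averages, and 2×2 confusion matrices, with
a single flag for the signature ordering: minority recall imbalanced <
rebalanced.

## Degenerate inputs and numerical conventions

Empty series, empty sets, constant beats under per-beat scaling,
mismatched lengths for the Euclidean distance, portions larger than
sets, and η < 0 all raise with named causes. Ties (best beat, medoid)
break to the lowest index. Non-finite losses abort training with a
diagnostic rather than continuing. CSV beat files round-trip at 9
significant digits; all float work is float64.

## Problem sizes used by the checks

The acceptance script and tests run deliberately scaled problems chosen
as this package's own smoke conditions: 200 enumeration pairs (lengths
≤ 6) for the distance oracles, 500 triples for the metric check,
records of 20–30 beats for QRS recall, a 90-beat default-schedule
training run for the 300-beat pool, the 500-beat/5-epoch classic-GAN
convergence run over 3 seeds, the scaled augmentation preset over 3
seeds, and a 40-beat/2-epoch CLI pipeline for bit-level determinism.

## Known limitations

- Wall-clock cost: the BiLSTM generator (34M parameters) and the WGAN
  are minutes-per-epoch at realistic set sizes on one CPU; the default
  smoke configurations keep them to seconds.
- Weight clipping is the only Lipschitz device for the WGAN; no
  gradient penalty.
- The fixture generator's idealizations (above) mean quantitative
  scores on synthetic conditions do not transfer to real recordings;
  the WFDB reader exists precisely so the same pipeline can be pointed
  at real single-lead records.
- The WFDB support is minimal: header + signal formats 212/16 + MIT
  annotation files, single channel, no calibration records or
  multi-segment files.
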