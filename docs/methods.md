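# Methods

This note documents the models and procedures `tnrkit` implements, the
parameters that matter, the conventions chosen where a convention had to be
chosen, and what the synthetic-data generators do and do not establish.

## Signal model and level conventions

All audio is mono, full scale ±1.0. The corrupted input is additive,
`x(t) = s(t) + v(t)`, with `s` clean speech and `v` a transient; mixtures
are constructed so the decomposition is known exactly, which is what makes
the ideal ratio mask computable.

Digital and acoustic levels are tied by one package-wide constant:
**0 dBFS RMS ≡ 100 dB SPL** (configurable in `set_level`). Speech presented
at 60 dB SPL therefore has RMS 0.01, leaving 40 dB of headroom for
transient peaks. No physical calibration is implied; the constant only
makes "60 dB SPL" reproducible arithmetic.

The speech-to-transient ratio is
`STR = 20·log10(rms(s) / peak_window_rms(v))`, where `peak_window_rms` is
the RMS of a 5-ms rectangular window centered on the transient's absolute
peak (clipped at signal edges — a choice; edge-peaked transients are
measured over the available samples). Mixing rescales the transient to hit
a requested STR within 0.01 dB and inserts it at a seeded-uniform position
wholly inside the sentence, one transient per sentence.

Frequency-dependent linear amplification (for hearing-impaired
presentation) is a 513-tap linear-phase FIR designed by frequency sampling
on a linear grid, with the user's gain table interpolated linearly in dB
and extrapolated flat. The group delay (n_taps−1)/2 is left in the output.

## Short-time analysis and overlap-add

Framing applies a periodic analysis window (Hann for the RNN chain, Tukey
α = 0.5 for MCTR — the taper ratio is a package choice, configurable);
synthesis applies the same window again and divides the accumulated signal
by the accumulated analysis×synthesis envelope, floored at 1e-8. This
weighted overlap-add is an exact identity for unmodified frames wherever
the envelope is above the floor, i.e. everywhere except a few tapered edge
samples, so round-trip tests measure the interior. Algorithmic latency is
`frame + (frame − hop)`: one frame of buffering plus one hop until the
final overlapped samples finish accumulating — 7.5 ms for 5-ms frames at
50% overlap.

## Gammatone features and the IRM

The 64-channel bank spans 50–8000 Hz with centers equally spaced in
ERB_N-number, `E(f) = 21.4·log10(4.37f/1000 + 1)`. Channel weighting is
spectral: squared 4th-order gammatone magnitude responses
`|H(f)|² = [1 + ((f − f_c)/b)²]^-4` with `b = 1.019·ERB_N(f_c)` evaluated
on the rfft grid of a 128-point FFT (5-ms frames are 80 samples at 16 kHz;
zero-padding to 128 refines the bin grid — a choice, as is the whole
spectral-weighting route rather than time-domain filtering; a test checks
the two routes agree per frame on narrowband inputs). A degenerate
single-channel bank centers at `f_lo`.

Frame energies are `Σ_k |X_jk|²·w_ik`. The IRM is `S²/(S²+V²)` per TF
unit; where `S² + V² < 1e-12` the mask is defined as 1 (silence carries no
transient, so nothing should be attenuated). Mask application maps the 64
channel gains to bin gains by the weight-normalized average
`g_k = Σ_i m_i w_ik / Σ_i w_ik`, which preserves unity gain under an
all-ones mask and never amplifies; phase is preserved.

## The mask-estimation network

Architecture: inputs of 3 timesteps (frames j−2, j−1, j; the first frames
are edge-replicated so the example count equals the frame count) × 64
features; LSTM layers of 128 and 64 units; fully connected 64-unit output.
The output activation is logistic — a package choice guaranteeing valid
masks. Training: Adam (lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e-8), MSE loss,
batch 1500, 5 epochs.

Features are log-compressed (`log10(e + 1e-10)`) and standardized per
channel with statistics estimated over the training corpus and stored in
the model archive. Raw energies span many orders of magnitude and
destabilize training; this choice is recorded so it can be ablated.

Forward pass, backpropagation through time and Adam are plain numpy
(~140k parameters; exact BPTT over 3 timesteps is cheap). Initialization
is Glorot-uniform with forget-gate bias 1, seeded; training is
bit-reproducible for a fixed (seed, data, config) on one platform.

## MCTR

Seven steps: resample to 22.05 kHz; 22-sample frames, hop 10, Tukey
window; 32-point FFT; group bins into 5 channels of (1, 1, 2, 3, 9);
detect `M_ij/RMS_ij > δ_i` with δ = (12, 21, 12, 8, 7); attenuate flagged
channels' bins by `α·R` dB, `R = 20log10(M_ij/RMS_ij)`, α = 0.467;
resample to 16 kHz. Conventions the description leaves open:

- A real 32-point FFT has 17 non-redundant bins; to honor the 16-bin
  layout, bins 1–16 are processed and DC passes through unmodified.
- The running reference is exponentially smoothed *squared* channel
  magnitude with a 200-ms time constant (configurable), **frozen** in any
  currently-flagged channel so a transient cannot inflate its own
  reference. References are floored at 1e-7 so near-silent channels do not
  divide by zero (a strong transient over silence then attenuates
  heavily, which is the intended direction).
- Attenuation is detection-gated: only channels satisfying the threshold
  rule are attenuated. Reading the `R > 0` branch alone would attenuate
  any above-average frame, contradicting the detection framing.
- Warm-up: references initialize from the first 100 ms with detection
  disabled.
- The signal is zero-padded by one frame at both ends before framing so
  every original sample is interior to the overlap-add envelope; α = 0
  reduces the whole chain to a resample round trip (≤ −35 dB error).

The weak/strong settings (α = 0.267 / 0.933) are reachable by parameter
but only the medium default is validated.

## Synthetic speech and transients

The generators state the world the evaluation runs in; their defaults are
not tuned to test outcomes.

- **Sentences**: durations drawn from N(1.98 s, 0.59 s) floored at 0.55 s
  (the floor truncates ~2% of draws and is required for the analysis
  windows to fit). The waveform is a drifting-f0 (80–300 Hz) harmonic
  complex with 1/k rolloff, three slowly wandering formant-like resonances,
  3–5 Hz raised-cosine syllabic modulation and smooth silent gaps. This
  emulates the spectro-temporal structure a mask estimator exploits; it is
  not intelligible speech, so metric *values* are not comparable to
  recorded-speech studies — only orderings and effect directions are.
- **Transients**: a half-cosine attack shorter than 1 ms, exponential
  decay over tens of ms, total duration ≤ 500 ms, optionally several
  progressively weaker strikes (0.8^k amplitudes, evenly spaced with
  jitter). Carriers are unit-modulus FM signals — a fixed tone, a smoothed
  noise-like frequency walk, or glides between a handful of resonant
  frequencies — so the waveform envelope follows the prescribed
  attack/decay exactly and the envelope constraints hold by construction
  *and* are verified by measurement in the tests.
- **Corpora**: train/test splits use per-item seeds derived from
  `blake2s("{seed}/{split}/{kind}/{index}")`, making train and test
  streams disjoint (unseen "talkers" and transients) and every mixture
  reproducible bit-for-bit from its manifest record. Defaults: train STRs
  {−5, −10, −15} dB with 15 transient generators, test STRs
  {−5, −10, −15, −20} dB with 9 disjoint ones.

## Objective metrics

**STOI** follows the published constants: 10 kHz internal rate, removal of
frames more than 40 dB below the loudest clean frame, 256/512 Hann STFT,
15 one-third-octave bands from 150 Hz, 384-ms (30-frame) segments,
band-envelope normalization with −15 dB clipping, averaged correlation.
No reference implementation is installable in this environment, so the
implementation is validated by its fixed points (identity → 1), bounds,
scale invariance and monotonicity under increasing noise rather than by a
cross-implementation diff.

**NCM**: 20 gammatone-spaced bands (150–7000 Hz), zero-phase FFT-domain
band filtering, Hilbert envelopes resampled to 25 Hz, per-band envelope
correlation r mapped to an apparent SNR `10log10(r²/(1−r²))` clipped to
±15 dB, transmission indices averaged with uniform weights (the variant is
selectable; the literature uses several weightings).

## Paired-comparison machinery

Trial lists cross (pair × presentation order × sentence × STR) exactly
once per cell — with the default 3 pairs, 12 sentences and 2 STRs this is
144 trials, which fixes the reading of "presented twice in both orders"
as once per order. The raw slider (±3, negative = first interval
preferred) is sign-corrected to a canonical convention: positive means the
pair's first-named condition is preferred, regardless of order. (The raw
assignment and plotting conventions conflict in the source material; the
canonical representation follows the plotting convention and the raw
slider is retained in the records.)

`wilcoxon_exact` drops exact zeros (reporting the reduced n), midranks
tied magnitudes, takes W as the smaller signed-rank sum, and computes the
two-tailed p by dynamic programming over the doubled (integer) ranks —
arithmetic identical to enumerating all 2ⁿ sign assignments, which the
test suite verifies against a literal enumeration oracle. No
multiple-comparison correction is applied by default; a Holm utility is
provided.

The simulated listener produces `clip(order-signed preference + N(0, σ), ±3)`
sliders: with σ = 0 the aggregation pipeline recovers the preferences
exactly, and under the null the exact test's measured type-I error at
α = .05 is within sampling error of its nominal (conservative) size.

## Known limitations

- Synthetic sentences are not intelligible speech; absolute metric values
  are only meaningful relative to each other within this stated world.
- The MCTR reference smoother (time constant, freeze rule) and the STOI
  cross-check are package conventions where the sources are silent or the
  environment lacks an oracle; both are flagged above.
- No real-time/streaming buffers, no multichannel audio, no GPU training;
  corpus scale is configurable but tests and the acceptance script run
  scaled-down replicas (tens of sentences, not 1600).
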