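"""Speech/transient mixing at controlled speech-to-transient ratios (STR),
plus synthetic generators so the whole toolchain runs without recordings.

STR is defined as ``20*log10(rms(clean) / peak_window_rms(transient))`` where
the transient's level is measured in a 5-ms rectangular window centered on
its absolute peak.  Lower STR means a more intense transient; −5 to −20 dB
covers the range from mildly to strongly intrusive.

The generators emulate the statistics of the corpora the method targets:
sentences are voiced harmonic complexes with drifting f0, slowly moving
formants, syllabic (3–5 Hz) amplitude modulation and silent gaps, with
durations drawn from a normal distribution (mean 1.98 s, SD 0.59 s);
transients have a 10–90% rise time under 1 ms, exponential decay over tens
of ms, total duration under a few hundred ms, and tonal, noisy or
multi-resonance spectra, optionally with several peaks (a bag of bottles
breaking rather than a single strike).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .signal_core import AudioSignal, rms, write_wav

__all__ = [
    "TransientParams",
    "MixtureSpec",
    "Mixture",
    "CorpusRecord",
    "Corpus",
    "peak_window_rms",
    "compute_str",
    "mix_at_str",
    "sample_duration",
    "synth_speech",
    "synth_transient",
    "build_corpus",
    "realize_record",
    "write_corpus",
    "item_seed",
]

DEFAULT_RATE = 16000.0
#: Sentence-duration distribution of the target corpus (seconds).
DURATION_MEAN_S = 1.98
DURATION_SD_S = 0.59
_MIN_DURATION_S = 0.55

TRAIN_STRS_DB = (-5.0, -10.0, -15.0)
TEST_STRS_DB = (-5.0, -10.0, -15.0, -20.0)

_PEAK_WINDOW_MS = 5.0


@dataclass(frozen=True)
class TransientParams:
    """Envelope and spectral description of a synthetic transient."""

    rise_time_ms: float = 0.5
    decay_time_ms: float = 30.0
    duration_ms: float = 120.0
    spectral_shape: str = "multi_peak"  # tonal | noisy | multi_peak
    n_peaks: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.rise_time_ms < 1.0):
            raise ValueError("rise time must be below 1 ms")
        if self.duration_ms > 500.0:
            raise ValueError("duration must not exceed 500 ms")
        if self.duration_ms <= 0 or self.decay_time_ms <= 0:
            raise ValueError("durations must be positive")
        if self.spectral_shape not in ("tonal", "noisy", "multi_peak"):
            raise ValueError(f"unknown spectral shape {self.spectral_shape!r}")
        if self.n_peaks < 1:
            raise ValueError("n_peaks must be at least 1")


@dataclass(frozen=True)
class MixtureSpec:
    """One sentence + one transient at a requested STR."""

    clean: AudioSignal
    transient: AudioSignal
    str_db: float
    insert_position: int | str = "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.transient) >= len(self.clean):
            raise ValueError("transient must be shorter than the sentence")
        if not np.isfinite(self.str_db):
            raise ValueError("str_db must be finite")


@dataclass(frozen=True)
class Mixture:
    """A realized mixture x = s + v with its exact components."""

    mixture: AudioSignal
    clean: AudioSignal
    transient_component: AudioSignal  # full-length, aligned v
    str_db: float
    position: int
    gain: float


def peak_window_rms(transient: AudioSignal, window_ms: float = _PEAK_WINDOW_MS) -> float:
    """RMS in a rectangular window centered on the absolute peak sample.

    The window is clipped at the signal edges, so a transient whose peak sits
    near a boundary is measured over the available samples.
    """
    win = int(round(window_ms * transient.rate / 1000.0))
    if len(transient) < win:
        raise ValueError(f"transient shorter than the {window_ms}-ms window")
    x = transient.samples
    peak = int(np.argmax(np.abs(x)))
    lo = max(0, peak - win // 2)
    hi = min(x.size, lo + win)
    lo = max(0, hi - win)
    return rms(x[lo:hi])


def compute_str(clean: AudioSignal, transient: AudioSignal) -> float:
    """STR in dB: clean-speech RMS over peak-window transient RMS."""
    s = rms(clean)
    v = peak_window_rms(transient)
    if s <= 0 or v <= 0:
        raise ValueError("STR is undefined for silent signals")
    return 20.0 * np.log10(s / v)


def mix_at_str(spec: MixtureSpec) -> Mixture:
    """Scale the transient to the requested STR and add it at a position
    drawn uniformly over placements that keep it wholly inside the sentence."""
    clean, transient = spec.clean, spec.transient
    if transient.rate != clean.rate:
        raise ValueError("clean and transient must share a sampling rate")
    gain = rms(clean) / (peak_window_rms(transient) * 10.0 ** (spec.str_db / 20.0))
    if spec.insert_position == "random":
        rng = np.random.default_rng(spec.seed)
        position = int(rng.integers(0, len(clean) - len(transient) + 1))
    else:
        position = int(spec.insert_position)
        if not (0 <= position <= len(clean) - len(transient)):
            raise ValueError("insert_position leaves the transient outside the sentence")
    v = np.zeros(len(clean))
    v[position : position + len(transient)] = transient.samples * gain
    v_sig = AudioSignal(v, clean.rate)
    x = AudioSignal(clean.samples + v, clean.rate)
    return Mixture(x, clean, v_sig, spec.str_db, position, gain)


def sample_duration(rng: np.random.Generator) -> float:
    """One sentence duration draw (s), floored to keep signals usable."""
    return max(float(rng.normal(DURATION_MEAN_S, DURATION_SD_S)), _MIN_DURATION_S)


def synth_speech(
    duration_s: float,
    seed: int = 0,
    rate: float = DEFAULT_RATE,
    f0_base_hz: float | None = None,
) -> AudioSignal:
    """Speech-like signal: harmonic source, formant coloring, syllabic gating.

    A drifting fundamental (80–300 Hz) excites a harmonic complex with 1/k
    rolloff; three slowly moving resonances emulate formants; a 3–5 Hz
    raised-cosine modulation plus occasional silent gaps emulates syllable
    structure.  Deterministic in (duration, seed, rate).
    """
    if duration_s <= 0.5:
        raise ValueError("sentence duration must exceed 0.5 s")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate

    if f0_base_hz is None:
        f0_base_hz = float(rng.uniform(90.0, 250.0))
    # slow log-frequency drift, ~1.5 semitone excursions
    drift = _smooth_noise(rng, n, rate, cutoff_hz=2.0)
    f0 = f0_base_hz * 2.0 ** (0.12 * drift)
    f0 = np.clip(f0, 80.0, 300.0)
    phase = 2.0 * np.pi * np.cumsum(f0) / rate

    source = np.zeros(n)
    max_harmonic = int(5000.0 / f0_base_hz)
    for k in range(1, max_harmonic + 1):
        if k * np.max(f0) >= rate / 2:
            break
        source += np.sin(k * phase + rng.uniform(0, 2 * np.pi)) / k

    # 3 formant-like resonances with slowly wandering centers
    colored = np.zeros(n)
    for lo, hi in ((280.0, 800.0), (900.0, 1800.0), (2000.0, 3000.0)):
        fc = float(rng.uniform(lo, hi))
        bw = 0.18 * fc
        r = np.exp(-np.pi * bw / rate)
        theta = 2.0 * np.pi * fc / rate
        b, a = [1.0 - r], [1.0, -2.0 * r * np.cos(theta), r * r]
        colored += sps.lfilter(b, a, source)

    # syllabic modulation and silent gaps
    f_syl = float(rng.uniform(3.0, 5.0))
    syllabic = 0.55 + 0.45 * np.sin(2 * np.pi * f_syl * t + rng.uniform(0, 2 * np.pi))
    gate = _smooth_noise(rng, n, rate, cutoff_hz=1.5)
    gate = 1.0 / (1.0 + np.exp(-4.0 * (gate + 1.0)))  # mostly on, occasional dips
    out = colored * syllabic * gate

    peak = np.max(np.abs(out))
    if peak > 0:
        out *= 0.3 / peak
    return AudioSignal(out, rate)


def _smooth_noise(rng: np.random.Generator, n: int, rate: float, cutoff_hz: float) -> np.ndarray:
    """Unit-variance Gaussian noise low-passed to ``cutoff_hz``."""
    raw = rng.standard_normal(n)
    sos = sps.butter(2, cutoff_hz, fs=rate, output="sos")
    smooth = sps.sosfiltfilt(sos, raw)
    sd = np.std(smooth)
    return smooth / sd if sd > 0 else smooth


def synth_transient(
    params: TransientParams,
    seed: int = 0,
    rate: float = DEFAULT_RATE,
) -> AudioSignal:
    """Transient with sub-millisecond attack and exponential decay.

    ``n_peaks > 1`` superimposes delayed, progressively weaker strikes
    (each above half the global peak) to emulate rattling/multi-impact
    sounds.  Deterministic in (params, seed, rate).
    """
    rng = np.random.default_rng(seed)
    n = int(round(params.duration_ms * rate / 1000.0))
    t = np.arange(n) / rate

    n_rise = max(int(round(params.rise_time_ms * rate / 1000.0)), 2)
    tau = params.decay_time_ms / 1000.0
    single = np.exp(-t / tau)
    single[:n_rise] *= 0.5 * (1.0 - np.cos(np.pi * np.arange(n_rise) / n_rise))

    # strikes spaced evenly (plus jitter) so successive peaks stay resolvable
    envelope = np.zeros(n)
    peak_amps = 0.8 ** np.arange(params.n_peaks)  # every strike above half peak
    if params.n_peaks == 1:
        offsets = np.array([0])
    else:
        span = max(n - n_rise - 1, params.n_peaks)
        base = np.linspace(0, span * (params.n_peaks - 1) / params.n_peaks, params.n_peaks)
        jitter = rng.uniform(0, 0.2 * span / params.n_peaks, size=params.n_peaks)
        offsets = np.clip((base + jitter).astype(int), 0, n - n_rise - 1)
        offsets[0] = 0
    for amp, off in zip(peak_amps, offsets):
        envelope[off:] = np.maximum(envelope[off:], amp * single[: n - off])

    # carriers are unit-modulus FM signals (cos of a phase integral), so the
    # waveform envelope follows the prescribed attack/decay exactly
    f_hi = min(7000.0, 0.45 * rate)
    if params.spectral_shape == "tonal":
        f_inst = np.full(n, rng.uniform(1000.0, 6000.0))
    elif params.spectral_shape == "noisy":
        walk = _smooth_noise(rng, n, rate, cutoff_hz=600.0)
        f_inst = 800.0 + (f_hi - 800.0) / (1.0 + np.exp(-walk))
    else:  # multi_peak spectrum: glide between a handful of resonant frequencies
        freqs = rng.uniform(800.0, f_hi, size=4)
        hold = max(int(0.003 * rate), 1)
        picks = rng.integers(0, freqs.size, size=n // hold + 1)
        f_inst = np.repeat(freqs[picks], hold)[:n]
        smooth = sps.windows.hann(max(int(0.001 * rate), 3))
        f_inst = np.convolve(f_inst, smooth / smooth.sum(), mode="same")
    phase = 2.0 * np.pi * np.cumsum(f_inst) / rate + rng.uniform(0, 2 * np.pi)
    carrier = np.cos(phase)

    out = envelope * carrier
    peak = np.max(np.abs(out))
    if peak > 0:
        out *= 0.9 / peak
    return AudioSignal(out, rate)


# --------------------------------------------------------------------------
# corpus construction


@dataclass(frozen=True)
class CorpusRecord:
    """Everything needed to regenerate one mixture bit-for-bit."""

    split: str
    index: int
    speech_seed: int
    duration_s: float
    transient_seed: int
    transient_params: TransientParams
    str_db: float
    position_seed: int
    rate: float = DEFAULT_RATE

    @property
    def key(self) -> str:
        return f"{self.split}-{self.index:04d}-str{int(self.str_db):+03d}"


@dataclass(frozen=True)
class Corpus:
    train: tuple
    test: tuple
    seed: int


def item_seed(seed: int, split: str, kind: str, index: int) -> int:
    """Stable 31-bit per-item seed; train/test streams never collide."""
    digest = hashlib.blake2s(f"{seed}/{split}/{kind}/{index}".encode()).digest()
    return int.from_bytes(digest[:4], "little") & 0x7FFFFFFF


def build_corpus(
    n_train: int,
    n_test: int,
    strs_train=TRAIN_STRS_DB,
    strs_test=TEST_STRS_DB,
    seed: int = 0,
    rate: float = DEFAULT_RATE,
    n_transients_train: int = 15,
    n_transients_test: int = 9,
) -> Corpus:
    """Manifest of train/test mixtures with disjoint speech and transient
    generator seeds (emulating unseen talkers and unseen transients).

    Each sentence is mixed at every STR of its split, mirroring the corpus
    recipe of 15 training / 9 test transient types and train STRs
    {−5, −10, −15} dB, test STRs {−5, −10, −15, −20} dB.
    """
    if n_train <= 0 or n_test <= 0:
        raise ValueError("counts must be positive")
    shapes = ("tonal", "noisy", "multi_peak")

    def records(split: str, n_sentences: int, strs, n_transients: int):
        dur_rng = np.random.default_rng(item_seed(seed, split, "durations", 0))
        param_rng = np.random.default_rng(item_seed(seed, split, "tparams", 0))
        tparams = []
        for _ in range(n_transients):
            tparams.append(
                TransientParams(
                    rise_time_ms=float(param_rng.uniform(0.2, 0.9)),
                    decay_time_ms=float(param_rng.uniform(15.0, 60.0)),
                    duration_ms=float(param_rng.uniform(60.0, 250.0)),
                    spectral_shape=shapes[int(param_rng.integers(len(shapes)))],
                    n_peaks=int(param_rng.integers(1, 4)),
                )
            )
        out = []
        for i in range(n_sentences):
            duration = sample_duration(dur_rng)
            t_idx = i % n_transients
            for str_db in strs:
                out.append(
                    CorpusRecord(
                        split=split,
                        index=i,
                        speech_seed=item_seed(seed, split, "speech", i),
                        duration_s=duration,
                        transient_seed=item_seed(seed, split, "transient", t_idx),
                        transient_params=tparams[t_idx],
                        str_db=float(str_db),
                        position_seed=item_seed(seed, split, f"pos{int(str_db)}", i),
                        rate=rate,
                    )
                )
        return tuple(out)

    return Corpus(
        train=records("train", n_train, strs_train, n_transients_train),
        test=records("test", n_test, strs_test, n_transients_test),
        seed=seed,
    )


def realize_record(record: CorpusRecord) -> Mixture:
    """Regenerate the mixture a record describes (pure function of the record)."""
    clean = synth_speech(record.duration_s, seed=record.speech_seed, rate=record.rate)
    transient = synth_transient(record.transient_params, seed=record.transient_seed, rate=record.rate)
    spec = MixtureSpec(
        clean=clean,
        transient=transient,
        str_db=record.str_db,
        insert_position="random",
        seed=record.position_seed,
    )
    return mix_at_str(spec)


def write_corpus(corpus: Corpus, out_dir) -> Path:
    """Materialize a corpus: WAV files plus a JSON-lines manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.jsonl"
    with open(manifest, "w") as fh:
        for record in corpus.train + corpus.test:
            mix = realize_record(record)
            wav = out_dir / f"{record.key}.wav"
            write_wav(wav, mix.mixture)
            entry = {
                "key": record.key,
                "split": record.split,
                "index": record.index,
                "speech_seed": record.speech_seed,
                "duration_s": record.duration_s,
                "transient_seed": record.transient_seed,
                "transient_params": vars(record.transient_params),
                "str_db": record.str_db,
                "position_seed": record.position_seed,
                "position": mix.position,
                "gain": mix.gain,
                "rate": record.rate,
                "wav": wav.name,
            }
            fh.write(json.dumps(entry) + "\n")
    return manifest
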