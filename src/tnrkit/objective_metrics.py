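"""Intrusive objective intelligibility metrics: STOI and NCM.

Both metrics compare band envelopes of a clean reference with a degraded or
processed rendering of the same utterance and return a value in [0, 1]
(higher = more intelligible).

STOI follows the published short-time procedure: both signals are resampled
to 10 kHz, frames in which the clean speech is more than 40 dB below its
most energetic frame are removed, a 256/512 Hann STFT is collapsed onto 15
one-third-octave bands from 150 Hz, and short-time (384-ms, 30-frame)
band-envelope segments are normalized, clipped at a -15 dB
signal-to-distortion floor and correlated.  The final value averages the
correlations over all bands and segments.

NCM filters both signals into 20 gammatone-spaced bands, extracts Hilbert
envelopes downsampled to 25 Hz, converts each band's envelope correlation r
into an apparent SNR ``10*log10(r^2/(1-r^2))`` clipped to [-15, 15] dB, and
averages the resulting transmission indices (uniform band weights by
default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signal_core import AudioSignal, FrameSpec, resample
from .tf_features import GammatoneBank, apply_mask, build_bank, compute_irm, erb_bandwidth, erb_number, erb_number_to_hz, extract_features
from .mixture_synth import Mixture, realize_record

__all__ = [
    "MetricResult",
    "stoi",
    "ncm",
    "evaluate_conditions",
    "standard_processors",
    "METRICS",
]

# STOI constants (documented values of the published algorithm)
_STOI_RATE = 10000.0
_STOI_FRAME = 256
_STOI_HOP = 128
_STOI_FFT = 512
_STOI_N_BANDS = 15
_STOI_LOW_CF = 150.0
_STOI_SEG = 30  # frames per 384-ms segment
_STOI_BETA_DB = -15.0
_STOI_DYN_RANGE_DB = 40.0

# NCM constants
_NCM_N_BANDS = 20
_NCM_F_LO = 150.0
_NCM_F_HI = 7000.0
_NCM_ENV_RATE = 25.0
_NCM_SNR_LIM_DB = 15.0


@dataclass(frozen=True)
class MetricResult:
    """A single metric value with its experimental labels."""

    name: str
    value: float
    condition: str | None = None
    str_db: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValueError("metric values lie in [0, 1]")

    def __float__(self) -> float:
        return self.value


def _check_pair(clean: AudioSignal, degraded: AudioSignal) -> None:
    if len(clean) != len(degraded):
        raise ValueError("clean and degraded must have equal lengths")
    if clean.rate != degraded.rate:
        raise ValueError("clean and degraded must share a sampling rate")
    if not np.any(clean.samples):
        raise ValueError("clean reference is silent")


def _remove_silent_frames(x: np.ndarray, y: np.ndarray):
    """Drop frames where the clean signal is > 40 dB below its loudest frame,
    and rebuild both signals from the retained Hann-windowed frames."""
    win = sps.windows.hann(_STOI_FRAME, sym=False)
    n_frames = 1 + (x.size - _STOI_FRAME) // _STOI_HOP
    idx = np.arange(_STOI_FRAME)[None, :] + _STOI_HOP * np.arange(n_frames)[:, None]
    xf = x[idx] * win
    yf = y[idx] * win
    energy_db = 20.0 * np.log10(np.linalg.norm(xf, axis=1) + 1e-20)
    keep = energy_db > energy_db.max() - _STOI_DYN_RANGE_DB
    xf, yf = xf[keep], yf[keep]
    n_keep = xf.shape[0]
    total = _STOI_FRAME + _STOI_HOP * (n_keep - 1)
    x_out = np.zeros(total)
    y_out = np.zeros(total)
    for j in range(n_keep):  # periodic hann at 50% overlap sums to unity
        sl = slice(j * _STOI_HOP, j * _STOI_HOP + _STOI_FRAME)
        x_out[sl] += xf[j]
        y_out[sl] += yf[j]
    return x_out, y_out


def _third_octave_matrix(rate: float):
    freqs = np.fft.rfftfreq(_STOI_FFT, d=1.0 / rate)
    centers = _STOI_LOW_CF * 2.0 ** (np.arange(_STOI_N_BANDS) / 3.0)
    H = np.zeros((_STOI_N_BANDS, freqs.size))
    for k, cf in enumerate(centers):
        lo, hi = cf / 2 ** (1 / 6), cf * 2 ** (1 / 6)
        H[k, (freqs >= lo) & (freqs < hi)] = 1.0
    return H


def stoi(clean: AudioSignal, degraded: AudioSignal, condition: str | None = None,
         str_db: float | None = None) -> MetricResult:
    """Short-time objective intelligibility of ``degraded`` against ``clean``."""
    _check_pair(clean, degraded)
    x = resample(clean, _STOI_RATE).samples
    y = resample(degraded, _STOI_RATE).samples
    if x.size < _STOI_FRAME:
        raise ValueError("signals too short for STOI")
    x, y = _remove_silent_frames(x, y)

    win = sps.windows.hann(_STOI_FRAME, sym=False)
    n_frames = 1 + (x.size - _STOI_FRAME) // _STOI_HOP
    if n_frames < _STOI_SEG:
        raise ValueError("fewer than 384 ms of active speech; STOI undefined")
    idx = np.arange(_STOI_FRAME)[None, :] + _STOI_HOP * np.arange(n_frames)[:, None]
    X = np.fft.rfft(x[idx] * win, n=_STOI_FFT, axis=1)
    Y = np.fft.rfft(y[idx] * win, n=_STOI_FFT, axis=1)
    H = _third_octave_matrix(_STOI_RATE)
    Xb = np.sqrt((np.abs(X) ** 2) @ H.T).T  # (bands, frames)
    Yb = np.sqrt((np.abs(Y) ** 2) @ H.T).T

    clip_gain = 10.0 ** (-_STOI_BETA_DB / 20.0)
    d_sum, count = 0.0, 0
    for m in range(_STOI_SEG, n_frames + 1):
        Xs = Xb[:, m - _STOI_SEG : m]
        Ys = Yb[:, m - _STOI_SEG : m]
        norm = np.linalg.norm(Xs, axis=1, keepdims=True) / (
            np.linalg.norm(Ys, axis=1, keepdims=True) + 1e-20
        )
        Ya = np.minimum(Ys * norm, Xs * (1.0 + clip_gain))
        Xc = Xs - Xs.mean(axis=1, keepdims=True)
        Yc = Ya - Ya.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(Xc, axis=1) * np.linalg.norm(Yc, axis=1) + 1e-20
        d_sum += float(np.sum((Xc * Yc).sum(axis=1) / denom))
        count += _STOI_N_BANDS
    value = float(np.clip(d_sum / count, 0.0, 1.0))
    return MetricResult("stoi", value, condition, str_db)


def _gammatone_band_signals(x: np.ndarray, rate: float, centers: np.ndarray) -> np.ndarray:
    """Zero-phase gammatone-magnitude band filtering via the FFT."""
    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / rate)
    b = 1.019 * erb_bandwidth(centers)
    ratio = (freqs[None, :] - centers[:, None]) / b[:, None]
    mag = (1.0 + ratio**2) ** -2  # 4th-order gammatone magnitude
    return np.fft.irfft(spectrum[None, :] * mag, n=x.size, axis=1)


def ncm(clean: AudioSignal, degraded: AudioSignal, condition: str | None = None,
        str_db: float | None = None, weights: np.ndarray | None = None) -> MetricResult:
    """Normalized covariance metric of ``degraded`` against ``clean``."""
    _check_pair(clean, degraded)
    rate = clean.rate
    cams = np.linspace(erb_number(_NCM_F_LO), erb_number(min(_NCM_F_HI, 0.45 * rate)), _NCM_N_BANDS)
    centers = erb_number_to_hz(cams)

    bands_x = _gammatone_band_signals(clean.samples, rate, centers)
    bands_y = _gammatone_band_signals(degraded.samples, rate, centers)
    env_x = np.abs(sps.hilbert(bands_x, axis=1))
    env_y = np.abs(sps.hilbert(bands_y, axis=1))

    decim = max(int(round(rate / _NCM_ENV_RATE)), 1)
    env_x = sps.resample_poly(env_x, 1, decim, axis=1)
    env_y = sps.resample_poly(env_y, 1, decim, axis=1)

    xc = env_x - env_x.mean(axis=1, keepdims=True)
    yc = env_y - env_y.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(xc, axis=1) * np.linalg.norm(yc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc * yc).sum(axis=1) / np.maximum(denom, 1e-20), 0.0)
    r2 = np.clip(r**2, 0.0, 1.0 - 1e-12)
    snr = np.clip(10.0 * np.log10(r2 / (1.0 - r2)), -_NCM_SNR_LIM_DB, _NCM_SNR_LIM_DB)
    ti = (snr + _NCM_SNR_LIM_DB) / (2.0 * _NCM_SNR_LIM_DB)
    if weights is None:
        weights = np.ones(_NCM_N_BANDS)
    value = float(np.clip(np.sum(weights * ti) / np.sum(weights), 0.0, 1.0))
    return MetricResult("ncm", value, condition, str_db)


METRICS = {"stoi": stoi, "ncm": ncm}


def standard_processors(model=None, bank: GammatoneBank | None = None,
                        spec: FrameSpec | None = None, mctr_config=None) -> dict:
    """The four evaluation conditions as mixture -> waveform callables.

    NP passes the mixture through untouched; trueIRM masks with the ideal
    ratio mask computed from the exact clean/transient components; RNN runs
    the trained estimator end-to-end; MCTR runs the seven-step algorithm.
    Conditions whose ingredients are not supplied are omitted.
    """
    from . import mctr as mctr_mod
    from . import rnn_tnr

    processors: dict = {"NP": lambda mix: mix.mixture}

    if bank is not None and spec is not None:
        def true_irm(mix: Mixture, bank=bank, spec=spec) -> AudioSignal:
            s = extract_features(mix.clean, bank, spec)
            v = extract_features(mix.transient_component, bank, spec)
            return apply_mask(mix.mixture, compute_irm(s, v), bank, spec)

        processors["trueIRM"] = true_irm

        if model is not None:
            processors["RNN"] = lambda mix, m=model, b=bank, s=spec: rnn_tnr.enhance(
                mix.mixture, m, b, s
            )

    cfg = mctr_config if mctr_config is not None else mctr_mod.MCTRConfig()
    processors["MCTR"] = lambda mix, c=cfg: mctr_mod.mctr_process(mix.mixture, c)
    return processors


def evaluate_conditions(records, processors: dict, metrics=("stoi", "ncm")) -> pd.DataFrame:
    """Tidy table of metric values: one row per (record, condition, metric).

    ``records`` are corpus records (regenerated on the fly); ``processors``
    maps condition labels to callables taking a :class:`Mixture`.
    """
    unknown = [m for m in metrics if m not in METRICS]
    if unknown:
        raise ValueError(f"unknown metrics {unknown}")
    rows = []
    for record in records:
        mix = realize_record(record)
        for condition, processor in processors.items():
            processed = processor(mix)
            for metric in metrics:
                result = METRICS[metric](mix.clean, processed, condition, record.str_db)
                rows.append(
                    {
                        "key": record.key,
                        "split": record.split,
                        "sentence": record.index,
                        "str_db": record.str_db,
                        "condition": condition,
                        "metric": metric,
                        "value": result.value,
                    }
                )
    return pd.DataFrame(rows)
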