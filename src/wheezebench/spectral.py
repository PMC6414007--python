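"""Shared spectral machinery.

Two estimators feed every spectral and cepstral feature:

* :func:`modified_periodogram` — a single power spectrum of the whole event,
  windowed with a high-dynamic-range Kaiser window (beta = 38 by default).
  Normalisation is chosen so the one-sided bin powers sum to the windowed
  signal's mean-square power divided by the window's mean-square (Parseval
  with window power normalisation).
* :func:`spectrogram` — framed short-time power spectra (32 ms frames,
  8 ms hop, Hann window by default) with the same per-frame normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import get_window

from .errors import DegenerateInputError, ParameterError

DEFAULT_KAISER_BETA = 38.0


@dataclass
class PowerSpectrum:
    freqs: np.ndarray  # Hz, ascending, 0..rate/2
    power: np.ndarray  # nonnegative power per bin

    @property
    def total_power(self) -> float:
        return float(np.sum(self.power))


@dataclass
class Spectrogram:
    frame_times: np.ndarray  # seconds, frame start times
    freqs: np.ndarray  # Hz
    power: np.ndarray  # (n_frames, n_bins), nonnegative

    @property
    def n_frames(self) -> int:
        return self.power.shape[0]


@dataclass(frozen=True)
class FrameConfig:
    """Short-time analysis geometry. Defaults: 32 ms frames, 8 ms hop."""

    width: float = 0.032
    hop: float = 0.008
    window: str = "hann"

    def __post_init__(self) -> None:
        if not (0 < self.hop <= self.width):
            raise ParameterError("FrameConfig requires 0 < hop <= width")

    def frame_samples(self, rate: float) -> int:
        return int(round(self.width * rate))

    def hop_samples(self, rate: float) -> int:
        return int(round(self.hop * rate))


def _one_sided_power(frames: np.ndarray, window: np.ndarray) -> np.ndarray:
    """One-sided power per bin, normalised so bins sum to
    sum((x*w)**2) / sum(w**2) for each frame (Parseval identity)."""
    n = frames.shape[-1]
    spec = np.abs(np.fft.rfft(frames * window, axis=-1)) ** 2
    if n % 2 == 0:
        spec[..., 1:-1] *= 2.0
    else:
        spec[..., 1:] *= 2.0
    return spec / (n * np.sum(window**2))


def modified_periodogram(
    x: np.ndarray, rate: float, kaiser_beta: float = DEFAULT_KAISER_BETA
) -> PowerSpectrum:
    """Whole-signal modified periodogram with a Kaiser(beta) window."""
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise DegenerateInputError("periodogram needs at least 8 samples")
    window = get_window(("kaiser", kaiser_beta), x.size, fftbins=True)
    power = _one_sided_power(x[np.newaxis, :], window)[0]
    freqs = np.fft.rfftfreq(x.size, d=1.0 / rate)
    return PowerSpectrum(freqs=freqs, power=power)


def spectrogram(x: np.ndarray, rate: float, cfg: FrameConfig | None = None) -> Spectrogram:
    """Framed one-sided power spectra; the last partial frame is dropped."""
    cfg = cfg or FrameConfig()
    x = np.asarray(x, dtype=float)
    frame_len = cfg.frame_samples(rate)
    hop = cfg.hop_samples(rate)
    if x.size < frame_len:
        raise DegenerateInputError(
            f"signal of {x.size} samples is shorter than one {frame_len}-sample frame"
        )
    frames = sliding_window_view(x, frame_len)[::hop]
    window = get_window(cfg.window, frame_len, fftbins=True)
    power = _one_sided_power(frames, window)
    freqs = np.fft.rfftfreq(frame_len, d=1.0 / rate)
    frame_times = np.arange(frames.shape[0]) * hop / rate
    return Spectrogram(frame_times=frame_times, freqs=freqs, power=power)
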