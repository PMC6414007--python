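"""The 105-feature acoustic feature bank for wheeze discrimination.

Feature families (name prefix, count):

* averaged power spectrum in 32 bands over 0-1950 Hz (``psd_*``, 32)
* 5-level db4 wavelet sub-band statistics and ratios (``wt_*``, 20)
* mel-frequency cepstral coefficients, whole event (``mfcc_*``, 13)
* order-6 LPC coefficients, prediction error and E(0)/E(4) (``lpc_*``, 8)
* percentile-frequency ratios (``pfr_*``, 4)
* spectral-entropy summaries + Renyi entropy of the amplitude
  distribution (``entropy_*``, ``renyi_entropy``, 4)
* band power ratio 250-800 Hz peak over 60-900 Hz mean (``power_ratio``)
* MPEG-7 audio-spectral-envelope flux (``ase_flux``)
* MPEG tonality index from spectral flatness (``tonality_index``)
* mean-crossing irregularity (``mci``)
* general time/spectral descriptors: roll-offs, quartile frequencies,
  moments, flatness, crest, slope, decrease, ZCR, RMS, ... (20)

All spectral descriptors derive from the shared whole-event Kaiser
periodogram; framed descriptors (tonality, ASE flux, spectral entropy)
use the 32 ms / 8 ms Hann spectrogram.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import pywt
from scipy.fft import dct

from .errors import DegenerateInputError, ParameterError
from .preprocessing import Event
from .spectral import (
    FrameConfig,
    PowerSpectrum,
    Spectrogram,
    modified_periodogram,
    spectrogram,
)

logger = logging.getLogger(__name__)

#: relative floor applied before every logarithm
EPS_REL = 1e-12
#: reported entropy ratio when the minimum frame entropy is exactly zero
ENTROPY_RATIO_SENTINEL = 1e6

N_PSD_BANDS = 32
PSD_BAND_TOP_HZ = 1950.0
N_WAVELET_LEVELS = 5
WAVELET = "db4"
N_MEL_FILTERS = 26
N_MFCC = 13
LPC_ORDER = 6
LPC_SEGMENT_SECONDS = 0.0512
LPC_OVERLAP_SECONDS = 0.0128
BRIGHTNESS_CUTOFF_HZ = 1500.0
ASE_LOW_EDGE_HZ = 62.5
ASE_HIGH_EDGE_HZ = 2000.0
TONALITY_SFM_FLOOR_DB = -60.0

FRAME_CONFIG = FrameConfig(width=0.032, hop=0.008, window="hann")

# ---------------------------------------------------------------------------
# canonical naming

_MISC_NAMES = [
    "rolloff_85", "rolloff_90", "rolloff_95",
    "f25", "f50", "f75",
    "rms", "brightness", "irregularity",
    "spec_kurtosis", "spec_skewness", "crest", "centroid", "decrease",
    "flatness", "slope", "spread", "zcr", "std", "band_power",
]

FEATURE_NAMES: list[str] = (
    [f"psd_{i:02d}" for i in range(1, N_PSD_BANDS + 1)]
    + [f"wt_mean_{j}" for j in range(1, 6)]
    + [f"wt_power_{j}" for j in range(1, 6)]
    + [f"wt_std_{j}" for j in range(1, 6)]
    + [f"wt_mean_ratio_{j}" for j in range(1, 6)]
    + [f"mfcc_{i:02d}" for i in range(1, N_MFCC + 1)]
    + [f"lpc_coef_{k}" for k in range(1, LPC_ORDER + 1)]
    + ["lpc_err6", "lpc_err_ratio_e0_e4"]
    + ["pfr_25_75", "pfr_25_90", "pfr_50_75", "pfr_50_90"]
    + ["entropy_diff", "entropy_ratio", "entropy_mean", "renyi_entropy"]
    + ["power_ratio", "ase_flux", "tonality_index", "mci"]
    + _MISC_NAMES
)

FAMILY_COUNTS = {
    "averaged_psd": 32, "wavelet": 20, "mfcc": 13, "lpc": 8,
    "percentile_ratio": 4, "entropy": 4, "power_ratio": 1, "ase_flux": 1,
    "tonality": 1, "mci": 1, "misc": 20,
}


def _floor(p: np.ndarray) -> np.ndarray:
    """Floor an array of powers at EPS_REL relative to its maximum."""
    top = float(np.max(p)) if p.size else 0.0
    if top <= 0:
        return np.full_like(p, 1.0)  # degenerate all-zero spectrum
    return np.maximum(p, EPS_REL * top)


# ---------------------------------------------------------------------------
# averaged power spectrum


def _averaged_psd(ps: PowerSpectrum) -> np.ndarray:
    width = PSD_BAND_TOP_HZ / N_PSD_BANDS
    out = np.zeros(N_PSD_BANDS)
    for j in range(N_PSD_BANDS):
        lo, hi = j * width, (j + 1) * width
        if j == N_PSD_BANDS - 1:
            mask = (ps.freqs >= lo) & (ps.freqs <= hi)
        else:
            mask = (ps.freqs >= lo) & (ps.freqs < hi)
        out[j] = float(np.mean(ps.power[mask])) if mask.any() else 0.0
    return out


def averaged_psd(event: Event) -> np.ndarray:
    """Whole-event periodogram power averaged in 32 equal bands, 0-1950 Hz."""
    return _averaged_psd(modified_periodogram(event.samples, event.rate))


# ---------------------------------------------------------------------------
# wavelet features


def _wavelet(x: np.ndarray) -> dict[str, float]:
    min_len = pywt.Wavelet(WAVELET).dec_len * 2**N_WAVELET_LEVELS
    if x.size < min_len:
        raise DegenerateInputError(
            f"wavelet family needs >= {min_len} samples, got {x.size}"
        )
    coeffs = pywt.wavedec(x, WAVELET, level=N_WAVELET_LEVELS)
    approx, details = coeffs[0], coeffs[:0:-1]  # details = [D1, ..., D5]
    out: dict[str, float] = {}
    abs_means = []
    for j, d in enumerate(details, start=1):
        abs_means.append(float(np.mean(np.abs(d))))
        out[f"wt_mean_{j}"] = abs_means[-1]
        out[f"wt_power_{j}"] = float(np.mean(d**2))
        out[f"wt_std_{j}"] = float(np.std(d))
    a_mean = float(np.mean(np.abs(approx)))
    for j in range(1, N_WAVELET_LEVELS):
        denom = abs_means[j]
        out[f"wt_mean_ratio_{j}"] = abs_means[j - 1] / denom if denom > 0 else 0.0
    out[f"wt_mean_ratio_{N_WAVELET_LEVELS}"] = (
        abs_means[-1] / a_mean if a_mean > 0 else 0.0
    )
    return out


def wavelet_features(event: Event) -> dict[str, float]:
    """db4 5-level detail statistics: |mean|, power, SD and adjacent-band
    |mean| ratios (D1/D2 ... D4/D5, then D5/A5)."""
    return _wavelet(event.samples)


# ---------------------------------------------------------------------------
# MFCC


def _hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(
    freqs: np.ndarray, n_filters: int = N_MEL_FILTERS, f_lo: float = 0.0, f_hi: float = 4000.0
) -> np.ndarray:
    """Triangular mel-spaced filters evaluated at the given bin frequencies."""
    edges = _mel_to_hz(np.linspace(_hz_to_mel(f_lo), _hz_to_mel(f_hi), n_filters + 2))
    fb = np.zeros((n_filters, freqs.size))
    for i in range(n_filters):
        lo, center, hi = edges[i], edges[i + 1], edges[i + 2]
        rise = (freqs - lo) / (center - lo)
        fall = (hi - freqs) / (hi - center)
        fb[i] = np.clip(np.minimum(rise, fall), 0.0, None)
    return fb


def cepstral_coefficients(log_energies: np.ndarray, n_coef: int = N_MFCC) -> np.ndarray:
    """Orthonormal DCT-II of the log filterbank energies, orders 0..n_coef-1."""
    return dct(np.asarray(log_energies, dtype=float), type=2, norm="ortho")[:n_coef]


def _mfcc(ps: PowerSpectrum) -> np.ndarray:
    fb = mel_filterbank(ps.freqs)
    energies = fb @ ps.power
    return cepstral_coefficients(np.log(_floor(energies)))


def mfcc_features(event: Event) -> np.ndarray:
    """13 MFCCs (orders 0..12) of the whole-event spectrum, 26 mel filters."""
    return _mfcc(modified_periodogram(event.samples, event.rate))


# ---------------------------------------------------------------------------
# LPC


def levinson_durbin(r: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Levinson-Durbin recursion on autocorrelations r[0..order].

    Returns (a, err): analysis-filter coefficients for
    A(z) = 1 + sum_k a_k z^-k and the prediction-error powers
    err[k] = E^(k) for k = 0..order.
    """
    a = np.zeros(order)
    err = np.zeros(order + 1)
    e = float(r[0])
    err[0] = e
    for i in range(1, order + 1):
        if e <= 0:
            err[i:] = max(e, 0.0)
            break
        acc = r[i] + float(np.dot(a[: i - 1], r[i - 1 : 0 : -1]))
        k = -acc / e
        a_prev = a[: i - 1].copy()
        a[: i - 1] = a_prev + k * a_prev[::-1]
        a[i - 1] = k
        e *= 1.0 - k * k
        err[i] = e
    return a, err


def _lpc(x: np.ndarray, rate: float) -> dict[str, float]:
    seg_len = int(round(LPC_SEGMENT_SECONDS * rate))
    hop = seg_len - int(round(LPC_OVERLAP_SECONDS * rate))
    if x.size < seg_len:
        raise DegenerateInputError(
            f"LPC family needs >= {seg_len} samples, got {x.size}"
        )
    coefs, err6, ratios = [], [], []
    for start in range(0, x.size - seg_len + 1, hop):
        seg = x[start : start + seg_len]
        r = np.correlate(seg, seg, mode="full")[seg_len - 1 : seg_len + LPC_ORDER]
        r = r / seg_len
        if r[0] <= 0:
            continue  # silent segment carries no predictor information
        a, err = levinson_durbin(r, LPC_ORDER)
        coefs.append(a)
        err6.append(err[LPC_ORDER])
        e4 = max(err[4], EPS_REL * err[0])
        ratios.append(err[0] / e4)
    if not coefs:
        raise DegenerateInputError("all LPC segments were silent")
    mean_a = np.mean(coefs, axis=0)
    out = {f"lpc_coef_{k}": float(mean_a[k - 1]) for k in range(1, LPC_ORDER + 1)}
    out["lpc_err6"] = float(np.mean(err6))
    out["lpc_err_ratio_e0_e4"] = float(np.mean(ratios))
    return out


def lpc_features(event: Event) -> dict[str, float]:
    """Segment-averaged order-6 LPC: 51.2 ms segments, 12.8 ms overlap."""
    return _lpc(event.samples, event.rate)


# ---------------------------------------------------------------------------
# percentile frequencies and ratios


def _percentile_freq(ps: PowerSpectrum, pct: float) -> float:
    """Lowest bin frequency where cumulative power reaches pct% of total."""
    cum = np.cumsum(ps.power)
    total = cum[-1]
    idx = int(np.searchsorted(cum, pct / 100.0 * total, side="left"))
    return float(ps.freqs[min(idx, ps.freqs.size - 1)])


def _percentiles(ps: PowerSpectrum) -> dict[str, float]:
    return {f"f{p}": _percentile_freq(ps, p) for p in (25, 50, 75, 90)}


def percentile_frequencies(event: Event) -> dict[str, float]:
    """Percentile frequencies f25/f50/f75/f90 and their four ratios."""
    ps = modified_periodogram(event.samples, event.rate)
    f = _percentiles(ps)
    return {**f, **_percentile_ratios(f)}


def _percentile_ratios(f: dict[str, float]) -> dict[str, float]:
    def ratio(a: float, b: float) -> float:
        return a / b if b > 0 else 1.0  # both percentiles in the DC bin

    return {
        "pfr_25_75": ratio(f["f25"], f["f75"]),
        "pfr_25_90": ratio(f["f25"], f["f90"]),
        "pfr_50_75": ratio(f["f50"], f["f75"]),
        "pfr_50_90": ratio(f["f50"], f["f90"]),
    }


# ---------------------------------------------------------------------------
# entropy features


def _frame_entropies(sg: Spectrogram) -> np.ndarray:
    sums = sg.power.sum(axis=1)
    keep = sums > 0
    p = sg.power[keep] / sums[keep, np.newaxis]
    logp = np.zeros_like(p)
    np.log2(p, out=logp, where=p > 0)
    return -(p * logp).sum(axis=1)


def _entropy_summary(sg: Spectrogram) -> dict[str, float]:
    if sg.n_frames < 2:
        raise DegenerateInputError("entropy family needs >= 2 frames")
    h = _frame_entropies(sg)
    if h.size < 2:
        raise DegenerateInputError("entropy family needs >= 2 nonzero frames")
    h_min, h_max = float(h.min()), float(h.max())
    if h_min == 0.0:
        logger.warning("minimum frame entropy is 0; entropy_ratio set to sentinel")
        ratio = ENTROPY_RATIO_SENTINEL
    else:
        ratio = h_max / h_min
    return {
        "entropy_diff": h_max - h_min,
        "entropy_ratio": ratio,
        "entropy_mean": float(h.mean()),
    }


def entropy_features(event: Event) -> dict[str, float]:
    """Range, ratio and mean of per-frame spectral entropy (bits)."""
    return _entropy_summary(spectrogram(event.samples, event.rate, FRAME_CONFIG))


def renyi_entropy(event: Event, alpha: float = 2.0, n_bins: int = 100) -> float:
    """Order-alpha Renyi entropy of the amplitude histogram on [-1, 1]."""
    counts, _ = np.histogram(event.samples, bins=n_bins, range=(-1.0, 1.0))
    p = counts / event.samples.size
    s = float(np.sum(p**alpha))
    return float(np.log(s) / (1.0 - alpha))


# ---------------------------------------------------------------------------
# power ratio


def _power_ratio(ps: PowerSpectrum) -> float:
    num = (ps.freqs >= 250.0) & (ps.freqs <= 800.0)
    den = (ps.freqs >= 60.0) & (ps.freqs <= 900.0)
    denom = float(np.mean(ps.power[den]))
    if denom <= 0:
        raise DegenerateInputError("no power in the 60-900 Hz band")
    return float(np.max(ps.power[num])) / denom


def power_ratio(event: Event) -> float:
    """Max bin power in 250-800 Hz over mean bin power in 60-900 Hz."""
    return _power_ratio(modified_periodogram(event.samples, event.rate))


# ---------------------------------------------------------------------------
# ASE flux


def ase_band_edges() -> np.ndarray:
    """Quarter-octave edges 62.5 * 2^(j/4), j = 0..20 (62.5-2000 Hz)."""
    return ASE_LOW_EDGE_HZ * 2.0 ** (np.arange(21) / 4.0)


def _ase_matrix(sg: Spectrogram) -> np.ndarray:
    """Per-frame audio spectral envelope in dB; 22 bands (below-edge band,
    20 quarter-octave bands, above-edge band)."""
    edges = np.concatenate(([0.0], ase_band_edges(), [np.inf]))
    n_bands = edges.size - 1
    env = np.zeros((sg.n_frames, n_bands))
    for b in range(n_bands):
        if b == n_bands - 1:
            mask = sg.freqs >= edges[b]
        else:
            mask = (sg.freqs >= edges[b]) & (sg.freqs < edges[b + 1])
        env[:, b] = sg.power[:, mask].sum(axis=1)
    return 10.0 * np.log10(_floor(env))


def _ase_flux(sg: Spectrogram) -> float:
    if sg.n_frames < 2:
        raise DegenerateInputError("ASE flux needs >= 2 frames")
    env = _ase_matrix(sg)
    return float(np.mean(np.linalg.norm(np.diff(env, axis=0), axis=1)))


def ase_flux(event: Event) -> float:
    """Mean Euclidean flux of the per-frame audio spectral envelope (dB)."""
    return _ase_flux(spectrogram(event.samples, event.rate, FRAME_CONFIG))


# ---------------------------------------------------------------------------
# tonality index


def _tonality(sg: Spectrogram) -> float:
    p = sg.power
    tops = p.max(axis=1)
    alphas = np.zeros(sg.n_frames)
    for t in range(sg.n_frames):
        if tops[t] <= 0:
            continue  # silent frame: noise-like by convention
        pf = np.maximum(p[t], EPS_REL * tops[t])
        sfm_db = 10.0 * np.log10(np.exp(np.mean(np.log(pf))) / np.mean(pf))
        alphas[t] = min(max(sfm_db / TONALITY_SFM_FLOOR_DB, 0.0), 1.0)
    return float(alphas.mean())


def tonality_index(event: Event) -> float:
    """Mean per-frame MPEG tonality: spectral flatness in dB mapped to
    [0, 1], where 1 = tonal and 0 = noise-like."""
    return _tonality(spectrogram(event.samples, event.rate, FRAME_CONFIG))


# ---------------------------------------------------------------------------
# mean crossing irregularity


def _attached_signs(d: np.ndarray) -> np.ndarray:
    """Signs of d with zeros attached to the preceding nonzero sign."""
    s = np.sign(d)
    nz = np.flatnonzero(s)
    if nz.size == 0:
        raise DegenerateInputError("signal never leaves its mean")
    idx = np.where(s != 0, np.arange(s.size), -1)
    np.maximum.accumulate(idx, out=idx)
    idx[idx < 0] = nz[0]  # leading zeros take the first nonzero sign
    return s[idx]


def _crossing_intervals(d: np.ndarray) -> np.ndarray:
    s = _attached_signs(d)
    crossings = np.flatnonzero(np.diff(s)) + 1
    if crossings.size < 3:
        raise DegenerateInputError("fewer than 3 mean crossings")
    return np.diff(crossings).astype(float)


def mean_crossing_irregularity(event: Event) -> float:
    """Coefficient of variation of the intervals between mean crossings."""
    x = event.samples
    intervals = _crossing_intervals(x - x.mean())
    return float(intervals.std() / intervals.mean())


# ---------------------------------------------------------------------------
# misc time and spectral features


def _zero_crossing_rate(x: np.ndarray, rate: float) -> float:
    s = _attached_signs(x)
    n_cross = int(np.count_nonzero(np.diff(s)))
    return n_cross * rate / x.size


def _misc(x: np.ndarray, rate: float, ps: PowerSpectrum) -> dict[str, float]:
    p, f = ps.power, ps.freqs
    total = float(p.sum())
    cum = np.cumsum(p)

    def cum_freq(pct: float) -> float:
        idx = int(np.searchsorted(cum, pct / 100.0 * total, side="left"))
        return float(f[min(idx, f.size - 1)])

    centroid = float(np.dot(f, p) / total)
    spread = float(np.sqrt(np.dot((f - centroid) ** 2, p) / total))
    if spread > 0:
        skew = float(np.dot((f - centroid) ** 3, p) / (total * spread**3))
        kurt = float(np.dot((f - centroid) ** 4, p) / (total * spread**4))
    else:
        logger.warning("zero spectral spread; skewness/kurtosis reported as 0")
        skew = kurt = 0.0
    pf = _floor(p)
    flatness = float(np.exp(np.mean(np.log(pf))) / np.mean(pf))
    fvar = float(np.var(f))
    slope = float(np.cov(f, p, bias=True)[0, 1] / fvar) / total
    decrease = float(np.sum((p[1:] - p[0]) / np.arange(1, p.size)) / np.sum(p[1:]))
    irregularity = float(np.sum(np.diff(p) ** 2) / np.sum(p**2))
    return {
        "rolloff_85": cum_freq(85), "rolloff_90": cum_freq(90), "rolloff_95": cum_freq(95),
        "f25": cum_freq(25), "f50": cum_freq(50), "f75": cum_freq(75),
        "rms": float(np.sqrt(np.mean(x**2))),
        "brightness": float(p[f >= BRIGHTNESS_CUTOFF_HZ].sum() / total),
        "irregularity": irregularity,
        "spec_kurtosis": kurt, "spec_skewness": skew,
        "crest": float(p.max() / p.mean()),
        "centroid": centroid, "decrease": decrease, "flatness": flatness,
        "slope": slope, "spread": spread,
        "zcr": _zero_crossing_rate(x, rate),
        "std": float(np.std(x)),
        "band_power": float(p[(f >= 150.0) & (f <= 2000.0)].sum()),
    }


def misc_features(event: Event) -> dict[str, float]:
    """The 20 general time/spectral descriptors (roll-offs, moments, ...)."""
    ps = modified_periodogram(event.samples, event.rate)
    return _misc(event.samples, event.rate, ps)


# ---------------------------------------------------------------------------
# feature vector assembly


@dataclass
class FeatureVector:
    """Ordered mapping of the 105 canonical feature names to scalars."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        if list(self.values) != FEATURE_NAMES:
            raise ParameterError("FeatureVector must carry the 105 canonical names in order")
        arr = np.fromiter(self.values.values(), dtype=float)
        if not np.all(np.isfinite(arr)):
            bad = [n for n, v in self.values.items() if not np.isfinite(v)]
            raise ParameterError(f"non-finite feature values: {bad}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_array(self) -> np.ndarray:
        return np.fromiter(self.values.values(), dtype=float)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, dtype=float)


def extract_all(event: Event) -> FeatureVector:
    """Compute all 105 features of one event in canonical order."""
    x, rate = event.samples, event.rate
    ps = modified_periodogram(x, rate)
    sg = spectrogram(x, rate, FRAME_CONFIG)

    out: dict[str, float] = {}

    def family(name: str, fn: Callable[[], None]) -> None:
        try:
            fn()
        except DegenerateInputError as exc:
            raise DegenerateInputError(f"{name} family: {exc}") from exc

    family("averaged_psd", lambda: out.update(
        {f"psd_{i + 1:02d}": v for i, v in enumerate(_averaged_psd(ps))}))
    family("wavelet", lambda: out.update(_wavelet(x)))
    family("mfcc", lambda: out.update(
        {f"mfcc_{i + 1:02d}": v for i, v in enumerate(_mfcc(ps))}))
    family("lpc", lambda: out.update(_lpc(x, rate)))
    pct = _percentiles(ps)
    family("percentile_ratio", lambda: out.update(_percentile_ratios(pct)))
    family("entropy", lambda: out.update(_entropy_summary(sg)))
    out["renyi_entropy"] = renyi_entropy(event)
    family("power_ratio", lambda: out.update({"power_ratio": _power_ratio(ps)}))
    family("ase_flux", lambda: out.update({"ase_flux": _ase_flux(sg)}))
    family("tonality", lambda: out.update({"tonality_index": _tonality(sg)}))
    family("mci", lambda: out.update({"mci": mean_crossing_irregularity(event)}))
    family("misc", lambda: out.update(_misc(x, rate, ps)))

    return FeatureVector(values={name: float(out[name]) for name in FEATURE_NAMES})


def feature_table(events: list[Event]) -> pd.DataFrame:
    """Feature matrix: one row per event, canonical columns plus
    ``recording_id`` and ``label``."""
    rows = []
    for ev in events:
        row = extract_all(ev).values.copy()
        row["recording_id"] = ev.recording_id
        row["label"] = ev.label
        rows.append(row)
    cols = ["recording_id", "label"] + FEATURE_NAMES
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# registry and timing


@dataclass(frozen=True)
class RegistryEntry:
    family: str
    domain: str  # relative cost class: time | spectral | cepstral | wavelet
    timing_fn: Callable[[Event], object]


def _registry() -> dict[str, RegistryEntry]:
    def spectral_fn(fn):
        return lambda ev: fn(modified_periodogram(ev.samples, ev.rate))

    def framed_fn(fn):
        return lambda ev: fn(spectrogram(ev.samples, ev.rate, FRAME_CONFIG))

    reg: dict[str, RegistryEntry] = {}

    def add(names, family, domain, fn):
        for n in names:
            reg[n] = RegistryEntry(family, domain, fn)

    add([f"psd_{i:02d}" for i in range(1, 33)], "averaged_psd", "spectral",
        spectral_fn(_averaged_psd))
    wt_names = [f"wt_{kind}_{j}" for kind in ("mean", "power", "std", "mean_ratio")
                for j in range(1, 6)]
    add(wt_names, "wavelet", "wavelet", lambda ev: _wavelet(ev.samples))
    add([f"mfcc_{i:02d}" for i in range(1, 14)], "mfcc", "cepstral", spectral_fn(_mfcc))
    add([f"lpc_coef_{k}" for k in range(1, 7)] + ["lpc_err6", "lpc_err_ratio_e0_e4"],
        "lpc", "time", lambda ev: _lpc(ev.samples, ev.rate))
    add(["pfr_25_75", "pfr_25_90", "pfr_50_75", "pfr_50_90"], "percentile_ratio",
        "spectral", spectral_fn(lambda ps: _percentile_ratios(_percentiles(ps))))
    add(["entropy_diff", "entropy_ratio", "entropy_mean"], "entropy", "spectral",
        framed_fn(_entropy_summary))
    add(["renyi_entropy"], "entropy", "time", renyi_entropy)
    add(["power_ratio"], "power_ratio", "spectral", spectral_fn(_power_ratio))
    add(["ase_flux"], "ase_flux", "spectral", framed_fn(_ase_flux))
    add(["tonality_index"], "tonality", "spectral", framed_fn(_tonality))
    add(["mci"], "mci", "time", mean_crossing_irregularity)
    # time-domain misc descriptors need no transform
    add(["rms"], "misc", "time", lambda ev: float(np.sqrt(np.mean(ev.samples**2))))
    add(["std"], "misc", "time", lambda ev: float(np.std(ev.samples)))
    add(["zcr"], "misc", "time", lambda ev: _zero_crossing_rate(ev.samples, ev.rate))
    spectral_misc = [n for n in _MISC_NAMES if n not in ("rms", "std", "zcr")]
    add(spectral_misc, "misc", "spectral",
        lambda ev: _misc(ev.samples, ev.rate,
                         modified_periodogram(ev.samples, ev.rate)))
    return {name: reg[name] for name in FEATURE_NAMES}


FEATURE_REGISTRY: dict[str, RegistryEntry] = _registry()


def timing_profile(
    events: list[Event], repetitions: int = 1, features: list[str] | None = None
) -> dict[str, float]:
    """Mean wall-clock seconds to extract each feature, including any
    transform it needs. Only the relative ranking is meaningful."""
    if repetitions < 1:
        raise ParameterError("repetitions must be >= 1")
    if not events:
        raise ParameterError("timing_profile needs at least one event")
    names = features if features is not None else FEATURE_NAMES
    out: dict[str, float] = {}
    for name in names:
        fn = FEATURE_REGISTRY[name].timing_fn
        t0 = time.perf_counter()
        for _ in range(repetitions):
            for ev in events:
                fn(ev)
        out[name] = (time.perf_counter() - t0) / (repetitions * len(events))
    return out
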