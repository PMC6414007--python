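"""Recording ingestion and event preprocessing.

Respiratory recordings arrive at arbitrary sample rates and levels. Every
annotated event is put through the same conditioning chain before feature
extraction:

1. fifth-order Butterworth band-pass 150-2000 Hz at the native rate
   (removes heart sounds / DC below 150 Hz, limits the band to the range
   where respiratory information lives),
2. polyphase resampling to 8000 Hz,
3. peak amplitude scaling into [-1, 1].

The order is fixed: filtering happens at the native rate, scaling last.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

from .errors import AnnotationError, DegenerateInputError, InputFormatError, ParameterError

TARGET_RATE = 8000
BAND_LOW_HZ = 150.0
BAND_HIGH_HZ = 2000.0
FILTER_ORDER = 5
#: events shorter than this cannot support two 32 ms analysis frames
MIN_EVENT_SECONDS = 0.064

WHEEZE = "wheeze"
NORMAL = "normal"
LABELS = (WHEEZE, NORMAL)


@dataclass
class Recording:
    """A mono audio recording with its native sample rate."""

    samples: np.ndarray
    rate: float
    recording_id: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ParameterError("Recording.samples must be one-dimensional")
        if self.samples.size == 0:
            raise ParameterError("Recording.samples must be non-empty")
        if not self.rate > 0:
            raise ParameterError("Recording.rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass(frozen=True)
class Annotation:
    """One labelled respiratory event inside a recording, in seconds."""

    recording_id: str
    start: float
    end: float
    label: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"annotation [{self.start}, {self.end}] for {self.recording_id!r} is not a valid interval"
            )
        if self.label not in LABELS:
            raise AnnotationError(f"label {self.label!r} not in {LABELS}")


@dataclass
class Event:
    """A preprocessed respiratory event: 8 kHz, peak-scaled to [-1, 1]."""

    samples: np.ndarray
    label: str
    recording_id: str
    rate: int = TARGET_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate != TARGET_RATE:
            raise ParameterError(f"Event rate must be {TARGET_RATE} Hz")
        if self.samples.size < MIN_EVENT_SECONDS * TARGET_RATE:
            raise DegenerateInputError(
                f"event of {self.samples.size / TARGET_RATE * 1e3:.1f} ms is shorter "
                f"than the {MIN_EVENT_SECONDS * 1e3:.0f} ms minimum"
            )

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


def load_recording(path: str | Path) -> Recording:
    """Read a WAV file (PCM or IEEE float); keeps the first channel only."""
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # scipy raises assorted ValueError/struct errors
        raise InputFormatError(f"cannot read WAV file {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim > 1:
        data = data[:, 0]
    if data.size == 0:
        raise InputFormatError(f"{path} contains no samples")
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return Recording(samples=data.astype(float), rate=float(rate), recording_id=path.stem)


def _bandpass_sos(rate: float) -> np.ndarray:
    if rate <= 2 * BAND_HIGH_HZ:
        raise ParameterError(
            f"sample rate {rate} Hz cannot represent the {BAND_HIGH_HZ} Hz band edge"
        )
    return signal.butter(
        FILTER_ORDER, [BAND_LOW_HZ, BAND_HIGH_HZ], btype="bandpass", fs=rate, output="sos"
    )


def bandpass_filter(x: np.ndarray, rate: float) -> np.ndarray:
    """Causal fifth-order Butterworth band-pass, 150-2000 Hz."""
    x = np.asarray(x, dtype=float)
    return signal.sosfilt(_bandpass_sos(rate), x)


def resample_to_8k(x: np.ndarray, rate: float) -> np.ndarray:
    """Polyphase rational resampling to 8000 samples/second."""
    x = np.asarray(x, dtype=float)
    if not rate > 0:
        raise ParameterError("rate must be positive")
    if rate == TARGET_RATE:
        return x.copy()
    frac = Fraction(TARGET_RATE, int(round(rate)))
    return signal.resample_poly(x, frac.numerator, frac.denominator)


def amplitude_scale(x: np.ndarray) -> np.ndarray:
    """Divide by the peak absolute value so max|x| = 1."""
    x = np.asarray(x, dtype=float)
    peak = np.max(np.abs(x)) if x.size else 0.0
    if peak == 0:
        raise DegenerateInputError("cannot amplitude-scale an all-zero signal")
    return x / peak


def preprocess_segment(x: np.ndarray, rate: float) -> np.ndarray:
    """Full conditioning chain: band-pass at native rate, resample, scale."""
    return amplitude_scale(resample_to_8k(bandpass_filter(x, rate), rate))


def cut_events(recording: Recording, annotations: list[Annotation]) -> list[Event]:
    """Slice annotated segments out of a recording and preprocess each."""
    events = []
    for ann in annotations:
        if ann.recording_id != recording.recording_id:
            raise AnnotationError(
                f"annotation for {ann.recording_id!r} applied to recording "
                f"{recording.recording_id!r}"
            )
        if ann.end > recording.duration + 1e-9:
            raise AnnotationError(
                f"annotation end {ann.end}s exceeds recording duration "
                f"{recording.duration:.3f}s"
            )
        lo = int(round(ann.start * recording.rate))
        hi = int(round(ann.end * recording.rate))
        segment = recording.samples[lo:hi]
        events.append(
            Event(
                samples=preprocess_segment(segment, recording.rate),
                label=ann.label,
                recording_id=recording.recording_id,
            )
        )
    return events


def events_from_recordings(
    recordings: list[Recording], annotations: list[Annotation]
) -> list[Event]:
    """Cut and preprocess every annotated event across many recordings."""
    by_rec: dict[str, list[Annotation]] = {}
    for ann in annotations:
        by_rec.setdefault(ann.recording_id, []).append(ann)
    known = {rec.recording_id for rec in recordings}
    orphans = set(by_rec) - known
    if orphans:
        raise AnnotationError(f"annotations reference unknown recordings: {sorted(orphans)}")
    events: list[Event] = []
    for rec in recordings:
        events.extend(cut_events(rec, by_rec.get(rec.recording_id, [])))
    return events


def read_annotations(path: str | Path) -> list[Annotation]:
    """Read an annotation CSV with header recording_id,start_s,end_s,label."""
    df = pd.read_csv(path)
    required = {"recording_id", "start_s", "end_s", "label"}
    if not required.issubset(df.columns):
        raise InputFormatError(
            f"annotation file {path} must have columns {sorted(required)}"
        )
    return [
        Annotation(
            recording_id=str(row.recording_id),
            start=float(row.start_s),
            end=float(row.end_s),
            label=str(row.label),
        )
        for row in df.itertuples()
    ]


def write_annotations(annotations: list[Annotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "recording_id": [a.recording_id for a in annotations],
            "start_s": [a.start for a in annotations],
            "end_s": [a.end for a in annotations],
            "label": [a.label for a in annotations],
        }
    ).to_csv(path, index=False)
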