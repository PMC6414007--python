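import numpy as np
import pytest

import wheezebench as wb
from wheezebench.preprocessing import Event


def make_event(samples, label="normal", recording_id="rec000", scale=True):
    """Wrap raw samples (8 kHz) into an Event, peak-scaling by default."""
    samples = np.asarray(samples, dtype=float)
    if scale:
        samples = samples / np.max(np.abs(samples))
    return Event(samples=samples, label=label, recording_id=recording_id)


@pytest.fixture
def sine_event():
    """1 s of a 500 Hz sinusoid whose zeros fall between samples."""
    t = np.arange(8000) / 8000.0
    return make_event(np.sin(2 * np.pi * 500 * t + 0.3), label="wheeze")


@pytest.fixture
def noise_event():
    rng = np.random.default_rng(42)
    return make_event(rng.standard_normal(8000))


@pytest.fixture(scope="session")
def small_dataset():
    """A small in-memory synthetic dataset exercising the full pipeline."""
    cfg = wb.SynthConfig(
        n_recordings=10, events_per_recording=(4, 5), native_rate=8000, seed=7
    )
    return wb.gen_dataset(cfg)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    events = wb.events_from_recordings(
        small_dataset.recordings, small_dataset.annotations
    )
    return wb.feature_table(events)
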