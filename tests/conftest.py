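import numpy as np
import pytest

from resptex.audio import AudioRecording
from resptex.synth import SynthSpec, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def sine_recording():
    """One second of a 100 Hz sine at 44.1 kHz."""
    rate = 44100.0
    t = np.arange(int(rate)) / rate
    return AudioRecording(np.sin(2 * np.pi * 100.0 * t), rate, source_id="sine")


@pytest.fixture(scope="session")
def clean_breath_recording():
    """Synthetic non-sputum recording with 3 ground-truth cycles at 20 dB SNR."""
    spec = SynthSpec(seed=42, snr_db=20.0, duration=10.0)
    rec, truth, _ = generate_recording(spec)
    rec.source_id = "clean"
    rec.patient_id = "P0"
    return rec, truth


@pytest.fixture(scope="session")
def sputum_recording():
    """Synthetic crackle-bearing recording with ground truth."""
    spec = SynthSpec(seed=43, snr_db=20.0, duration=10.0, sputum=True)
    rec, truth, _ = generate_recording(spec)
    rec.source_id = "sputum"
    rec.patient_id = "P1"
    return rec, truth


def jaccard(a, b):
    """Interval overlap on half-open sample spans."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0
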