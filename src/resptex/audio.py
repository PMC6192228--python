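"""Audio I/O, framing and manifest handling.

Recordings are mono amplitude traces nominally in [-1, 1]. WAV files are
read and written through :mod:`scipy.io.wavfile`; integer PCM is rescaled
to float by the full-scale value of its bit depth, stereo is averaged to
mono. A cohort of recordings is described by a CSV manifest with columns
``source_id, path, patient_id, label``.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import windows

LABEL_NON_SPUTUM = 0
LABEL_SPUTUM = 1
LABEL_UNKNOWN = -1

_WINDOWS = {
    "hamming": lambda L: windows.hamming(L, sym=True),
    "blackman_harris": lambda L: windows.blackmanharris(L, sym=True),
    "rect": lambda L: np.ones(L),
}

MANIFEST_COLUMNS = ["source_id", "path", "patient_id", "label"]


@dataclass
class AudioRecording:
    """A mono respiratory-sound recording.

    Parameters
    ----------
    samples : ndarray
        Amplitude samples, dimensionless, nominally in [-1, 1].
    rate : float
        Sampling frequency in Hz (the acquisition device records at 44100).
    source_id : str
        Recording identifier.
    patient_id : str or None
        Subject identifier, used for leave-one-patient-out splits.
    label : int
        1 = sputum, 0 = non-sputum, -1 = unknown.
    """

    samples: np.ndarray
    rate: float
    source_id: str = ""
    patient_id: str | None = None
    label: int = LABEL_UNKNOWN

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional (mono)")
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def duration_seconds(self) -> float:
        return len(self.samples) / self.rate

    def slice(self, start: int, end: int) -> "AudioRecording":
        """Half-open sample slice [start, end) keeping the metadata."""
        return AudioRecording(
            self.samples[start:end], self.rate, self.source_id,
            self.patient_id, self.label,
        )


@dataclass
class FrameSet:
    """Windowed frames of a signal: M frames x L samples.

    ``frames[i]`` is the raw slice starting at ``i * hop`` multiplied
    elementwise by the analysis window.
    """

    frames: np.ndarray
    frame_length: int
    hop: int
    window_name: str
    rate: float
    window: np.ndarray = field(repr=False, default=None)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def window_coefficients(window_name: str, L: int) -> np.ndarray:
    """Symmetric analysis-window coefficients of length L."""
    try:
        return _WINDOWS[window_name](L)
    except KeyError:
        raise ValueError(
            f"unsupported window {window_name!r}; choose from {sorted(_WINDOWS)}"
        ) from None


def read_wav(path: str | os.PathLike) -> AudioRecording:
    """Read a WAV file to a mono recording with samples scaled to [-1, 1].

    PCM integer data is divided by the full-scale magnitude of its dtype
    (32768 for 16-bit); IEEE-float data is taken as-is. Stereo channels are
    averaged.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such audio file: {path}")
    rate, data = wavfile.read(path)
    if data.size == 0:
        raise ValueError(f"zero-length audio: {path}")
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).min)
        samples = data.astype(np.float64) / -scale
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV sample encoding {data.dtype}")
    return AudioRecording(samples, float(rate),
                          source_id=os.path.splitext(os.path.basename(path))[0])


def write_wav(path: str | os.PathLike, rec: AudioRecording,
              subtype: str = "float") -> None:
    """Write a recording as 16-bit PCM (``subtype='pcm16'``) or 32-bit float."""
    if subtype == "pcm16":
        clipped = np.clip(rec.samples, -1.0, 32767.0 / 32768.0)
        wavfile.write(path, int(rec.rate),
                      np.round(clipped * 32768.0).astype(np.int16))
    elif subtype == "float":
        wavfile.write(path, int(rec.rate), rec.samples.astype(np.float32))
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")


def make_frames(rec: AudioRecording, L: int, hop: int,
                window_name: str = "hamming") -> FrameSet:
    """Split a recording into M = floor((n - L)/hop) + 1 windowed frames.

    A signal shorter than one frame yields an empty FrameSet with a warning
    rather than an error, so downstream stages see "no frames" not a crash.
    """
    if L <= 0 or hop <= 0:
        raise ValueError("frame length and hop must be positive")
    w = window_coefficients(window_name, L)
    n = len(rec.samples)
    if n < L:
        warnings.warn(
            f"signal of {n} samples shorter than frame length {L}; no frames",
            stacklevel=2,
        )
        frames = np.empty((0, L))
    else:
        M = (n - L) // hop + 1
        idx = hop * np.arange(M)[:, None] + np.arange(L)[None, :]
        frames = rec.samples[idx] * w[None, :]
    return FrameSet(frames, L, hop, window_name, rec.rate, window=w)


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read a cohort manifest CSV (source_id, path, patient_id, label)."""
    df = pd.read_csv(path, dtype={"source_id": str, "patient_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns {missing}")
    return df


def write_manifest(path: str | os.PathLike, rows: Sequence[dict] | pd.DataFrame) -> None:
    df = pd.DataFrame(rows)[MANIFEST_COLUMNS]
    df.to_csv(path, index=False)
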