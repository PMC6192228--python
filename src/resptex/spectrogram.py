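"""STFT power spectrogram of a respiratory cycle and its dB image.

Each frame of N samples (default 1024, 4-term Blackman-Harris window,
50% overlap) is transformed by a one-sided DFT; the squared magnitude
E(n, k) = |X(n, k)|^2 is the power spectrum, and 10*log10(E) — clamped at
a configurable floor so silent bins do not produce -inf — is the gray
image handed to the texture stage. Rows index frequency (bin k, low
frequency first), columns index time (frame n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import rfft

from .audio import AudioRecording, make_frames

DEFAULT_N_FFT = 1024
DEFAULT_HOP = 512
DEFAULT_WINDOW = "blackman_harris"
DEFAULT_FLOOR_DB = -120.0


@dataclass
class Spectrogram:
    power: np.ndarray      # (N/2 + 1 bins, n frames), linear power, >= 0
    db_image: np.ndarray   # 10*log10(power) clamped at floor_db
    n_fft: int
    hop: int
    window_name: str
    rate: float
    floor_db: float = DEFAULT_FLOOR_DB

    @property
    def n_bins(self) -> int:
        return self.power.shape[0]

    @property
    def n_frames(self) -> int:
        return self.power.shape[1]

    @property
    def freq_resolution(self) -> float:
        """Hz per frequency bin."""
        return self.rate / self.n_fft


def stft(segment: AudioRecording, n_fft: int = DEFAULT_N_FFT,
         hop: int = DEFAULT_HOP,
         window_name: str = DEFAULT_WINDOW) -> np.ndarray:
    """One-sided STFT matrix X(k, n): column n is the N-point DFT of the
    windowed frame starting at sample n*hop."""
    if len(segment.samples) < n_fft:
        raise ValueError(
            f"segment of {len(segment.samples)} samples is shorter than the "
            f"minimum of n_fft={n_fft}"
        )
    frames = make_frames(segment, n_fft, hop, window_name)
    return rfft(frames.frames, n_fft, axis=1).T


def power_spectrum(stft_matrix: np.ndarray) -> np.ndarray:
    """E(k, n) = |X|^2 = X * conj(X), real and non-negative."""
    return (stft_matrix * np.conj(stft_matrix)).real


def db_transform(power: np.ndarray,
                 floor_db: float = DEFAULT_FLOOR_DB) -> np.ndarray:
    """10*log10(power) with entries at or below the floor clamped to floor_db."""
    floor_power = 10.0 ** (floor_db / 10.0)
    return 10.0 * np.log10(np.maximum(power, floor_power))


def cycle_spectrogram(segment: AudioRecording, n_fft: int = DEFAULT_N_FFT,
                      hop: int = DEFAULT_HOP,
                      window_name: str = DEFAULT_WINDOW,
                      floor_db: float = DEFAULT_FLOOR_DB) -> Spectrogram:
    """Full spectrogram of one respiratory-cycle segment."""
    X = stft(segment, n_fft, hop, window_name)
    E = power_spectrum(X)
    return Spectrogram(E, db_transform(E, floor_db), n_fft, hop,
                       window_name, segment.rate, floor_db)


def save_db_image(spec: Spectrogram, path: str) -> None:
    """Export the dB image as a grayscale PNG (time -> x, low frequency at
    the bottom) for visual inspection."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    extent = (0, spec.n_frames * spec.hop / spec.rate,
              0.0, spec.n_bins * spec.freq_resolution)
    ax.imshow(spec.db_image, origin="lower", aspect="auto", cmap="gray",
              extent=extent)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
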