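"""Respiratory-cycle segmentation by short-time autocorrelation.

The recording is framed (Hamming window, non-overlapping 1024-sample frames
by default) and each frame's autocorrelation

    R_i(k) = sum_{m=0}^{L-1-k} [x_i(m) w(m)] [x_i(m+k) w(m+k)]

is reduced to its maximum over lags k = 1..k_max (lag 0 is plain frame
energy and is excluded by default). Breath activity raises this envelope
far above the noise floor C0, estimated as the mean envelope over the
leading silent portion of the recording. Two thresholds derived from the
floor, C1 = a*C0 (cycle start/end) and C2 = b*C0 (cycle confirmation),
drive a hysteresis state machine; dips below C1 shorter than the maximum
silence time Ts (the inspiration-expiration pause) are bridged into the
surrounding cycle.

Because R_i(k) scales with the square of the signal amplitude and so does
C0, the segmentation is invariant to global gain.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft

from .audio import AudioRecording, FrameSet, make_frames

logger = logging.getLogger(__name__)

DEFAULT_FRAME_LENGTH = 1024
DEFAULT_LAG_BOUND = 400
DEFAULT_SILENCE_DURATION = 0.025  # s of assumed leading silence
DEFAULT_A = 2.0
DEFAULT_B = 4.0
DEFAULT_TS = 0.3  # s, max bridged silence inside one cycle


@dataclass
class AutocorrEnvelope:
    """Per-frame maximum of the short-time autocorrelation."""

    max_corr: np.ndarray
    frame_length: int
    lag_bound: int
    hop: int
    rate: float

    @property
    def n_frames(self) -> int:
        return len(self.max_corr)


@dataclass
class SegmentationThresholds:
    """Noise-floor derived thresholds C1 = a*C0, C2 = b*C0 and silence cap Ts."""

    C0: float
    a: float = DEFAULT_A
    b: float = DEFAULT_B
    Ts: float = DEFAULT_TS
    C1: float = field(init=False)
    C2: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0 < self.a <= self.b:
            raise ValueError(f"need 0 < a <= b, got a={self.a}, b={self.b}")
        if self.Ts < 0:
            raise ValueError("Ts must be non-negative")
        self.C1 = self.a * self.C0
        self.C2 = self.b * self.C0


@dataclass
class RespiratoryCycle:
    """One detected breath cycle, half-open in samples and frames."""

    start_sample: int
    end_sample: int
    start_frame: int
    end_frame: int
    label: int = -1

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample

    def duration_seconds(self, rate: float) -> float:
        return self.n_samples / rate


def frame_autocorrelation(frame: np.ndarray, k_max: int) -> np.ndarray:
    """Linear autocorrelation R(k), k = 0..k_max, of one windowed frame.

    Computed via FFT with zero padding (exact linear autocorrelation up to
    floating point); equivalent to the direct double loop over products of
    sample pairs separated by k.
    """
    L = len(frame)
    if k_max >= L:
        raise ValueError(f"k_max={k_max} must be < frame length {L}")
    nfft = next_fast_len(2 * L)
    spec = rfft(frame, nfft)
    acf = irfft(spec * np.conj(spec), nfft)
    return acf[: k_max + 1]


def short_time_autocorr(frames: FrameSet, k_max: int = DEFAULT_LAG_BOUND,
                        include_lag_zero: bool = False) -> AutocorrEnvelope:
    """Per-frame max of R_i(k) over k = 1..k_max (0..k_max if requested).

    Lag 0 equals the frame energy and would swamp the correlation structure
    the thresholds rely on, so it is excluded by default.
    """
    L = frames.frame_length
    if k_max >= L:
        raise ValueError(f"k_max={k_max} must be < frame length {L}")
    if frames.n_frames == 0:
        env = np.empty(0)
    else:
        nfft = next_fast_len(2 * L)
        spec = rfft(frames.frames, nfft, axis=1)
        acf = irfft(spec * np.conj(spec), nfft, axis=1)[:, : k_max + 1]
        lo = 0 if include_lag_zero else 1
        env = acf[:, lo:].max(axis=1)
    return AutocorrEnvelope(env, L, k_max, frames.hop, frames.rate)


def estimate_noise_floor(env: AutocorrEnvelope,
                         silence_duration: float = DEFAULT_SILENCE_DURATION) -> float:
    """Noise floor C0: mean envelope over frames starting in the leading silence.

    The first `silence_duration` seconds of the recording are assumed silent;
    C0 averages the envelope of every frame whose start sample lies within
    that window. If the window is shorter than one hop, the first frame alone
    is used.
    """
    if env.n_frames == 0:
        raise ValueError("empty envelope: cannot estimate noise floor")
    n_silent = int(np.sum(env.hop * np.arange(env.n_frames)
                          < silence_duration * env.rate))
    n_silent = max(n_silent, 1)
    return float(np.mean(env.max_corr[:n_silent]))


def segment_cycles(env: AutocorrEnvelope,
                   thr: SegmentationThresholds) -> list[RespiratoryCycle]:
    """Hysteresis segmentation of the autocorrelation envelope.

    A candidate cycle opens at the first frame strictly above C1; it is
    confirmed only if some frame within it strictly exceeds C2; it closes
    when the envelope stays at or below C1 for longer than Ts (shorter dips
    are bridged). Unconfirmed candidates are dropped (logged, not raised).
    Frame spans are converted to half-open sample intervals via hop and L.
    """
    ts_frames = int(np.floor(thr.Ts * env.rate / env.hop))
    active = env.max_corr > thr.C1
    cycles: list[RespiratoryCycle] = []
    n_dropped = 0

    in_cycle = False
    start = last_active = 0
    confirmed = False

    def close(end_active: int) -> None:
        nonlocal n_dropped
        if confirmed:
            s_frame, e_frame = start, end_active + 1
            cycles.append(RespiratoryCycle(
                start_sample=s_frame * env.hop,
                end_sample=(e_frame - 1) * env.hop + env.frame_length,
                start_frame=s_frame,
                end_frame=e_frame,
            ))
        else:
            n_dropped += 1

    for i in range(env.n_frames):
        if active[i]:
            if not in_cycle:
                in_cycle, start, confirmed = True, i, False
            last_active = i
            if env.max_corr[i] > thr.C2:
                confirmed = True
        elif in_cycle and (i - last_active) > ts_frames:
            close(last_active)
            in_cycle = False
    if in_cycle:
        close(last_active)
    if n_dropped:
        logger.info("dropped %d candidate cycles never exceeding C2", n_dropped)
    return cycles


def segment_recording(rec: AudioRecording,
                      frame_length: int = DEFAULT_FRAME_LENGTH,
                      hop: int | None = None,
                      k_max: int = DEFAULT_LAG_BOUND,
                      a: float = DEFAULT_A,
                      b: float = DEFAULT_B,
                      Ts: float = DEFAULT_TS,
                      silence_duration: float = DEFAULT_SILENCE_DURATION,
                      window_name: str = "hamming",
                      include_lag_zero: bool = False) -> list[RespiratoryCycle]:
    """End-to-end segmentation: frame, autocorrelate, threshold.

    Non-overlapping frames (hop = frame length) keep the leading silence
    window aligned with whole frames. Returned cycles inherit the
    recording's label.
    """
    hop = frame_length if hop is None else hop
    frames = make_frames(rec, frame_length, hop, window_name)
    if frames.n_frames == 0:
        return []
    env = short_time_autocorr(frames, k_max, include_lag_zero)
    C0 = estimate_noise_floor(env, silence_duration)
    if C0 <= 0:
        # digitally-silent lead-in (all-zero samples): fall back to a tiny
        # positive floor so thresholds stay meaningful
        positive = env.max_corr[env.max_corr > 0]
        C0 = float(positive.min()) * 1e-3 if positive.size else 0.0
        if C0 == 0.0:
            return []
        warnings.warn("zero noise floor; using fallback floor", stacklevel=2)
    thr = SegmentationThresholds(C0=C0, a=a, b=b, Ts=Ts)
    cycles = segment_cycles(env, thr)
    n = len(rec.samples)
    for c in cycles:
        c.end_sample = min(c.end_sample, n)
        c.label = rec.label
    return cycles
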