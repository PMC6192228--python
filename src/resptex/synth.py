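"""Synthetic tracheal-sound generator with ground-truth cycle boundaries.

No public corpus of intubated-patient tracheal recordings exists, so the
test bed synthesizes them. A recording is a low-level Gaussian noise
floor on which breath cycles are superimposed at a fixed breathing
rhythm: each cycle is band-limited flow noise (default 100-2000 Hz) with
raised-cosine onsets/offsets, an inspiration phase and an expiration
phase separated by a short pause (which exercises the segmenter's
max-silence bridging). A "sputum" recording additionally carries short
broadband crackle transients — exponentially damped sinusoids, the
standard lung-crackle model — at Poisson times inside the cycles; these
are what produce the vertical striations in the spectrogram that the
texture features respond to.

All randomness flows through one seeded :class:`numpy.random.Generator`,
so a given spec is bit-reproducible.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfilt

from .audio import (LABEL_NON_SPUTUM, LABEL_SPUTUM, AudioRecording,
                    write_manifest, write_wav)

#: cohort scale mirroring the study population: 12 intubated patients,
#: 145/272 of the sound samples sputum-positive
DEFAULT_N_PATIENTS = 12
DEFAULT_SPUTUM_FRACTION = 145 / 272


@dataclass
class SynthSpec:
    """Parameters of one synthetic recording.

    Defaults: 44.1 kHz sampling (the acquisition device's rate), 18
    breaths/min with a 1.2 s inter-cycle gap, flow noise in 100-2000 Hz at
    15 dB above the floor, and — when ``sputum`` is set — ~25 crackles/s
    of 2-8 ms in 500-8000 Hz at four times the breath RMS.
    """

    rate: float = 44100.0
    duration: float = 10.0
    breaths_per_min: float = 18.0
    cycle_noise_band: tuple[float, float] = (100.0, 2000.0)
    silence_gap: float = 1.2        # s between consecutive cycles
    intra_pause: float = 0.15       # s inspiration-expiration pause (< Ts)
    sputum: bool = False
    crackle_rate: float = 25.0      # expected crackles per active second
    crackle_duration: tuple[float, float] = (0.002, 0.008)
    crackle_band: tuple[float, float] = (500.0, 8000.0)
    crackle_gain: float = 4.0       # crackle peak over breath RMS
    snr_db: float = 15.0            # breath RMS over floor RMS, dB
    floor_sigma: float = 0.01       # noise-floor standard deviation
    lead_in: float = 0.3            # s of silence before the first cycle
    ramp: float = 0.1               # s raised-cosine onset/offset
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rate", "duration", "snr_db", "floor_sigma"):
            if getattr(self, name) <= 0 and name not in ("snr_db",):
                raise ValueError(f"{name} must be positive")

    @property
    def period(self) -> float:
        return 60.0 / self.breaths_per_min

    @property
    def cycle_duration(self) -> float:
        return self.period - self.silence_gap


def _raised_cosine_burst(n: int, n_ramp: int) -> np.ndarray:
    """Unit-height envelope with raised-cosine attack and release."""
    env = np.ones(n)
    n_ramp = min(n_ramp, n // 2)
    if n_ramp > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = r
        env[-n_ramp:] = r[::-1]
    return env


def _bandpass_sos(band: tuple[float, float], rate: float):
    nyq = rate / 2.0
    lo = max(band[0] / nyq, 1e-4)
    hi = min(band[1] / nyq, 0.999)
    return butter(4, (lo, hi), btype="bandpass", output="sos")


def generate_recording(spec: SynthSpec
                       ) -> tuple[AudioRecording, list[tuple[int, int]], int]:
    """Synthesize one recording.

    Returns the recording, the ground-truth cycle intervals as half-open
    sample spans, and the label (1 sputum / 0 non-sputum).
    """
    if spec.breaths_per_min > 0 and spec.cycle_duration <= 0:
        raise ValueError(
            f"infeasible spec: silence gap {spec.silence_gap}s leaves no room "
            f"in a {spec.period:.2f}s breathing period")
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.rate))
    signal = rng.normal(0.0, spec.floor_sigma, n)
    truth: list[tuple[int, int]] = []

    if spec.breaths_per_min > 0:
        breath_rms = spec.floor_sigma * 10.0 ** (spec.snr_db / 20.0)
        sos = _bandpass_sos(spec.cycle_noise_band, spec.rate)
        n_ramp = int(spec.ramp * spec.rate)
        active_dur = spec.cycle_duration - spec.intra_pause
        insp_dur = 0.4 * active_dur
        exp_dur = 0.6 * active_dur
        t0 = spec.lead_in
        while t0 + spec.cycle_duration <= spec.duration:
            s0 = int(round(t0 * spec.rate))
            s1 = int(round((t0 + spec.cycle_duration) * spec.rate))
            phases = [
                (s0, s0 + int(insp_dur * spec.rate), 1.0),
                (s1 - int(exp_dur * spec.rate), s1, 0.8),
            ]
            active_idx = []
            for a, b, rel in phases:
                m = b - a
                if m <= 0:
                    continue
                flow = sosfilt(sos, rng.normal(0.0, 1.0, m))
                rms = np.sqrt(np.mean(flow ** 2))
                flow *= (breath_rms * rel / rms) * _raised_cosine_burst(m, n_ramp)
                signal[a:b] += flow
                active_idx.append((a, b))
            if spec.sputum:
                _add_crackles(signal, active_idx, breath_rms, spec, rng)
            truth.append((s0, s1))
            t0 += spec.period

    rec = AudioRecording(signal, spec.rate,
                         label=LABEL_SPUTUM if spec.sputum else LABEL_NON_SPUTUM)
    return rec, truth, rec.label


def _add_crackles(signal: np.ndarray, active_idx: list[tuple[int, int]],
                  breath_rms: float, spec: SynthSpec,
                  rng: np.random.Generator) -> None:
    """Superimpose damped-sinusoid crackle transients at Poisson times."""
    for a, b in active_idx:
        seg_dur = (b - a) / spec.rate
        n_crackles = rng.poisson(spec.crackle_rate * seg_dur)
        starts = rng.uniform(a, b, size=n_crackles).astype(int)
        for s in starts:
            dur = rng.uniform(*spec.crackle_duration)
            m = max(int(dur * spec.rate), 8)
            f = rng.uniform(*spec.crackle_band)
            t = np.arange(m) / spec.rate
            burst = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            burst *= np.exp(-t / (dur / 4.0))
            e = min(s + m, len(signal))
            signal[s:e] += spec.crackle_gain * breath_rms * burst[: e - s]


@dataclass
class Cohort:
    """A generated patient cohort: recordings, labels and ground truth."""

    manifest: pd.DataFrame
    recordings: list[AudioRecording]
    truth: dict[str, list[tuple[int, int]]] = field(default_factory=dict)


def generate_cohort(n_patients: int = DEFAULT_N_PATIENTS,
                    recordings_per_patient: int = 6,
                    sputum_fraction: float = DEFAULT_SPUTUM_FRACTION,
                    seed: int = 0,
                    base_spec: SynthSpec | None = None,
                    jitter_sigma: float = 0.2,
                    out_dir: str | os.PathLike | None = None) -> Cohort:
    """Generate a multi-patient cohort with per-patient parameter jitter.

    Breathing rate and SNR receive per-patient multiplicative lognormal
    jitter (sigma = ``jitter_sigma``) to emulate inter-subject variability,
    which keeps leave-one-patient-out evaluation honest. The sputum label
    count is ``round(total * sputum_fraction)``, spread as evenly as
    possible across patients and shuffled within each patient. With
    ``out_dir`` set, WAV files, ``manifest.csv`` and ``truth.json`` are
    written there; recordings are always returned in memory too.
    """
    if n_patients < 1 or recordings_per_patient < 1:
        raise ValueError("counts must be positive")
    base = base_spec if base_spec is not None else SynthSpec()
    rng = np.random.default_rng(seed)

    total = n_patients * recordings_per_patient
    n_pos = int(round(total * sputum_fraction))
    labels = np.zeros(total, dtype=int)
    # spread positives evenly over patients, remainder to the first patients
    per_patient = np.full(n_patients, n_pos // n_patients)
    per_patient[: n_pos % n_patients] += 1
    pos = 0
    for p in range(n_patients):
        block = labels[p * recordings_per_patient:(p + 1) * recordings_per_patient]
        block[: per_patient[p]] = 1
        rng.shuffle(block)
        pos += per_patient[p]

    rows, recordings, truth = [], [], {}
    for p in range(n_patients):
        patient_id = f"P{p + 1:02d}"
        bpm = base.breaths_per_min * rng.lognormal(0.0, jitter_sigma)
        snr = base.snr_db * rng.lognormal(0.0, jitter_sigma)
        for r in range(recordings_per_patient):
            source_id = f"{patient_id}_R{r + 1:02d}"
            label = int(labels[p * recordings_per_patient + r])
            spec = replace(base, breaths_per_min=bpm, snr_db=snr,
                           sputum=bool(label),
                           seed=int(rng.integers(2 ** 31)))
            rec, intervals, _ = generate_recording(spec)
            rec.source_id = source_id
            rec.patient_id = patient_id
            recordings.append(rec)
            truth[source_id] = intervals
            path = ""
            if out_dir is not None:
                path = os.path.join(str(out_dir), f"{source_id}.wav")
                write_wav(path, rec, subtype="pcm16")
            rows.append({"source_id": source_id, "path": path,
                         "patient_id": patient_id, "label": label})
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        write_manifest(os.path.join(str(out_dir), "manifest.csv"), manifest)
        with open(os.path.join(str(out_dir), "truth.json"), "w") as fh:
            json.dump({k: [list(iv) for iv in v] for k, v in truth.items()},
                      fh, indent=1)
    return Cohort(manifest=manifest, recordings=recordings, truth=truth)
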