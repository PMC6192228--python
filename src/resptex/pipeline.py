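"""End-to-end feature extraction: recording -> cycles -> texture table.

Ties the stages together with the study defaults (1024-sample Hamming
frames and 400-lag autocorrelation for segmentation; 1024-point
Blackman-Harris STFT at 50% overlap; 16-level GLCM at distance 1) and
produces the per-cycle feature table consumed by the selection,
classifier and evaluation modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from . import segmentation as seg
from . import spectrogram as sp
from . import texture as tx
from .audio import AudioRecording, read_manifest, read_wav
from .segmentation import RespiratoryCycle

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Stage parameters, exposed in one place for the CLI and scripts."""

    # segmentation
    frame_length: int = seg.DEFAULT_FRAME_LENGTH
    k_max: int = seg.DEFAULT_LAG_BOUND
    a: float = seg.DEFAULT_A
    b: float = seg.DEFAULT_B
    Ts: float = seg.DEFAULT_TS
    silence_duration: float = seg.DEFAULT_SILENCE_DURATION
    segment_window: str = "hamming"
    # spectrogram
    n_fft: int = sp.DEFAULT_N_FFT
    stft_hop: int = sp.DEFAULT_HOP
    stft_window: str = sp.DEFAULT_WINDOW
    floor_db: float = sp.DEFAULT_FLOOR_DB
    # texture
    gray_levels: int = tx.DEFAULT_GRAY_LEVELS
    distance: int = tx.DEFAULT_DISTANCE
    classic_inertia: bool = False


def segment_recording(rec: AudioRecording,
                      cfg: PipelineConfig = PipelineConfig()
                      ) -> list[RespiratoryCycle]:
    return seg.segment_recording(
        rec, frame_length=cfg.frame_length, k_max=cfg.k_max, a=cfg.a,
        b=cfg.b, Ts=cfg.Ts, silence_duration=cfg.silence_duration,
        window_name=cfg.segment_window)


def cycle_features(rec: AudioRecording, cycle: RespiratoryCycle,
                   cfg: PipelineConfig = PipelineConfig()) -> dict[str, float]:
    """Texture attributes of one segmented cycle."""
    spec = sp.cycle_spectrogram(
        rec.slice(cycle.start_sample, cycle.end_sample),
        n_fft=cfg.n_fft, hop=cfg.stft_hop, window_name=cfg.stft_window,
        floor_db=cfg.floor_db)
    feats = tx.feature_vector(spec, distance=cfg.distance,
                              n_levels=cfg.gray_levels,
                              classic_inertia=cfg.classic_inertia)
    return feats.as_dict()


def extract_features(recordings: Iterable[AudioRecording],
                     cfg: PipelineConfig = PipelineConfig()) -> pd.DataFrame:
    """Per-cycle feature table over a collection of recordings.

    Columns: source_id, patient_id, cycle_index, label, start_sample,
    end_sample, then the 16 texture attributes. Cycles shorter than one
    STFT frame are skipped with a log message.
    """
    rows = []
    for rec in recordings:
        cycles = segment_recording(rec, cfg)
        for ci, cyc in enumerate(cycles):
            if cyc.n_samples < cfg.n_fft:
                logger.info("skipping cycle %d of %s: %d samples < n_fft",
                            ci, rec.source_id, cyc.n_samples)
                continue
            row = {"source_id": rec.source_id,
                   "patient_id": rec.patient_id,
                   "cycle_index": ci,
                   "label": rec.label,
                   "start_sample": cyc.start_sample,
                   "end_sample": cyc.end_sample}
            row.update(cycle_features(rec, cyc, cfg))
            rows.append(row)
    cols = ["source_id", "patient_id", "cycle_index", "label",
            "start_sample", "end_sample", *tx.FEATURE_NAMES]
    return pd.DataFrame(rows, columns=cols)


def extract_features_from_manifest(manifest_path: str,
                                   cfg: PipelineConfig = PipelineConfig()
                                   ) -> pd.DataFrame:
    """Read every WAV named in a manifest CSV and extract cycle features."""
    manifest = read_manifest(manifest_path)

    def _iter():
        for row in manifest.itertuples(index=False):
            rec = read_wav(row.path)
            rec.source_id = str(row.source_id)
            rec.patient_id = str(row.patient_id)
            rec.label = int(row.label)
            yield rec

    return extract_features(_iter(), cfg)
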