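"""Signal conditioning: bandpass filter, resample, MAD normalization, epoching.

The canonical order is filter -> resample -> normalize -> epoch; the CLI and
:func:`preprocess_recording` enforce it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .constants import BANDPASS_HIGH_HZ, BANDPASS_LOW_HZ, EPOCH_WINDOW_S, TARGET_RATE_HZ

logger = logging.getLogger(__name__)

VALID_LABELS = ("target", "distractor", "background")

#: event-table columns required everywhere; rt_s / fixation_latency_s are optional
EVENT_COLUMNS = ("onset_s", "label", "subject", "experiment", "condition")


@dataclass
class Recording:
    """Continuous multi-channel EEG for one subject in one experiment."""

    data: np.ndarray  # (n_channels, n_samples)
    sample_rate_hz: float
    channel_names: tuple[str, ...]
    subject: str
    experiment: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} data rows"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


@dataclass
class EventTable:
    """Per-event metadata rows (onset, class label, provenance, optional RT)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")
        bad = set(self.df["label"]) - set(VALID_LABELS)
        if bad:
            raise ValueError(f"unknown event labels: {sorted(bad)}")
        if (self.df["onset_s"] < 0).any():
            raise ValueError("event onsets must be non-negative")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def for_recording(self, rec: Recording) -> pd.DataFrame:
        sel = (self.df["subject"] == rec.subject) & (self.df["experiment"] == rec.experiment)
        return self.df[sel]


@dataclass
class EpochSet:
    """Fixed-length trials x channels x samples with binary labels.

    Targets and distractors map to the positive class (1), backgrounds to 0.
    """

    data: np.ndarray  # (n_trials, n_channels, n_samples)
    window: tuple[float, float]
    labels: np.ndarray  # (n_trials,) in {0, 1}
    meta: pd.DataFrame
    sample_rate_hz: float
    channel_names: tuple[str, ...] = ()
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        if len(self.labels) != self.data.shape[0] or len(self.meta) != self.data.shape[0]:
            raise ValueError("labels/meta misaligned with epochs")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.window[0] + np.arange(n) / self.sample_rate_hz


def bandpass_filter(
    rec: Recording, low_hz: float = BANDPASS_LOW_HZ, high_hz: float = BANDPASS_HIGH_HZ
) -> Recording:
    """Zero-phase 4th-order Butterworth bandpass, same shape and rate."""
    nyq = rec.sample_rate_hz / 2.0
    if not 0 < low_hz < high_hz:
        raise ValueError(f"need 0 < low < high, got ({low_hz}, {high_hz})")
    if high_hz >= nyq:
        raise ValueError(f"high edge {high_hz} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(4, [low_hz, high_hz], btype="bandpass", fs=rec.sample_rate_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=filtered.astype(rec.data.dtype, copy=False))


def resample(rec: Recording, target_hz: float = TARGET_RATE_HZ) -> Recording:
    """Polyphase rational downsampling; onsets stay valid because they are in seconds."""
    if target_hz > rec.sample_rate_hz:
        raise ValueError(
            f"upsampling {rec.sample_rate_hz} -> {target_hz} Hz is out of scope"
        )
    if target_hz == rec.sample_rate_hz:
        return replace(rec, data=rec.data.copy())
    frac = Fraction(target_hz / rec.sample_rate_hz).limit_denominator(1000)
    out = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return replace(rec, data=out.astype(rec.data.dtype, copy=False), sample_rate_hz=float(target_hz))


def compute_mad(data: np.ndarray) -> float:
    """median(|x - median(x)|) over the flattened array, no consistency constant."""
    flat = np.asarray(data).ravel()
    return float(np.median(np.abs(flat - np.median(flat))))


def mad_normalize(rec: Recording) -> Recording:
    mad = compute_mad(rec.data)
    if mad == 0:
        raise ValueError(
            f"recording (subject={rec.subject!r}, experiment={rec.experiment!r}) has zero MAD"
        )
    return replace(rec, data=(rec.data / mad).astype(rec.data.dtype, copy=False))


def epoch_events(
    rec: Recording,
    events: EventTable,
    window: tuple[float, float] = EPOCH_WINDOW_S,
) -> EpochSet:
    """Cut half-open fixed-length sample windows around each event onset.

    Start sample is ``round((onset + window[0]) * fs)``; the length is always
    ``round((window[1] - window[0]) * fs)`` samples. Events whose window falls
    outside the recording are skipped with a logged warning.
    """
    fs = rec.sample_rate_hz
    n_len = round((window[1] - window[0]) * fs)
    rows = events.for_recording(rec)
    epochs, kept_idx = [], []
    n_skipped = 0
    for idx, row in rows.iterrows():
        start = round((row["onset_s"] + window[0]) * fs)
        stop = start + n_len
        if start < 0 or stop > rec.n_samples:
            n_skipped += 1
            continue
        epochs.append(rec.data[:, start:stop])
        kept_idx.append(idx)
    if n_skipped:
        logger.warning(
            "skipped %d of %d events with windows outside recording %s/%s",
            n_skipped, len(rows), rec.subject, rec.experiment,
        )
    if epochs:
        data = np.stack(epochs)
    else:
        data = np.empty((0, rec.data.shape[0], n_len), dtype=rec.data.dtype)
    meta = rows.loc[kept_idx].reset_index(drop=True)
    labels = meta["label"].isin(("target", "distractor")).to_numpy(dtype=np.int64)
    return EpochSet(
        data=data,
        window=window,
        labels=labels,
        meta=meta,
        sample_rate_hz=fs,
        channel_names=rec.channel_names,
        n_skipped=n_skipped,
    )


def preprocess_recording(
    rec: Recording,
    low_hz: float = BANDPASS_LOW_HZ,
    high_hz: float = BANDPASS_HIGH_HZ,
    target_hz: float = TARGET_RATE_HZ,
) -> Recording:
    """The canonical chain: bandpass -> resample -> MAD normalize."""
    return mad_normalize(resample(bandpass_filter(rec, low_hz, high_hz), target_hz))
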