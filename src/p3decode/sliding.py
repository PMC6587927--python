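"""Sliding-window decoding: a time series of CNN outputs around each event.

Each output is the target-class probability for a 1 s epoch whose *start* time
labels the output, so the output at T = 0 uses the epoch [0, 1) s. The default
grid runs from 1 s before to 1 s after onset in 4-sample steps at 128 Hz,
producing 65 outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import constants as C
from .decoder import TrainedDecoder
from .preprocess import Recording

logger = logging.getLogger(__name__)

__all__ = ["DecodeTrace", "sliding_decode", "sliding_decode_events", "average_traces", "trace_grid"]


@dataclass
class DecodeTrace:
    """Per-window target probabilities for one trial, times = epoch starts."""

    times_s: np.ndarray
    probs: np.ndarray
    event_meta: pd.Series | dict

    def __post_init__(self) -> None:
        if len(self.times_s) != len(self.probs):
            raise ValueError("times and probs misaligned")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((self.probs < 0) | (self.probs > 1)):
            raise ValueError("probabilities outside [0, 1]")

    def center_times_s(self, epoch_len_s: float = 1.0) -> np.ndarray:
        """Re-index to epoch-center times, convenient for plotting."""
        return self.times_s + epoch_len_s / 2.0


def trace_grid(
    sample_rate_hz: float = C.TARGET_RATE_HZ,
    span_s: tuple[float, float] = C.DECODE_SPAN_S,
    stride_samples: int = C.DECODE_STRIDE_SAMPLES,
) -> np.ndarray:
    """Epoch-start times of the decoding grid (65 points by default)."""
    start = round(span_s[0] * sample_rate_hz)
    stop = round(span_s[1] * sample_rate_hz)
    return np.arange(start, stop + 1, stride_samples) / sample_rate_hz


def sliding_decode_events(
    decoder: TrainedDecoder,
    rec: Recording,
    onsets_s: Sequence[float],
    stride_samples: int = C.DECODE_STRIDE_SAMPLES,
    span_s: tuple[float, float] = C.DECODE_SPAN_S,
    epoch_len_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Decode many events at once; returns (times (n_win,), probs (n_events, n_win)).

    All windows from all events are batched through one prediction call.
    """
    fs = rec.sample_rate_hz
    n_len = round(epoch_len_s * fs)
    offsets = np.arange(round(span_s[0] * fs), round(span_s[1] * fs) + 1, stride_samples)
    times = offsets / fs
    onsets_s = np.asarray(onsets_s, dtype=float)

    starts = np.round(onsets_s * fs).astype(int)[:, None] + offsets[None, :]
    lo, hi = starts.min(), starts.max() + n_len
    if lo < 0 or hi > rec.n_samples:
        need_pre = -span_s[0]
        need_post = span_s[1] + epoch_len_s
        raise ValueError(
            f"insufficient data around events: each onset needs {need_pre:.2f} s before "
            f"and {need_post:.2f} s after within recording {rec.subject}/{rec.experiment}"
        )
    n_ev, n_win = starts.shape
    logger.info(
        "sliding decode: %d events, stride %d samples, %d windows each",
        n_ev, stride_samples, n_win,
    )
    probs = np.empty((n_ev, n_win))
    # bound the materialized epoch tensor to ~130 MB regardless of event count
    ev_chunk = max(1, 4096 // n_win)
    for e0 in range(0, n_ev, ev_chunk):
        chunk_starts = starts[e0 : e0 + ev_chunk].ravel()
        epochs = np.empty((len(chunk_starts), rec.data.shape[0], n_len), dtype=np.float32)
        for i, s in enumerate(chunk_starts):
            epochs[i] = rec.data[:, s : s + n_len]
        probs[e0 : e0 + ev_chunk] = decoder.predict_proba(epochs)[:, 1].reshape(-1, n_win)
    return times, probs


def sliding_decode(
    decoder: TrainedDecoder,
    rec: Recording,
    onset_s: float,
    stride_samples: int = C.DECODE_STRIDE_SAMPLES,
    span_s: tuple[float, float] = C.DECODE_SPAN_S,
    epoch_len_s: float = 1.0,
    event_meta: pd.Series | dict | None = None,
) -> DecodeTrace:
    """Decode one trial into a probability trace (65 outputs on the default grid)."""
    times, probs = sliding_decode_events(
        decoder, rec, [onset_s], stride_samples=stride_samples,
        span_s=span_s, epoch_len_s=epoch_len_s,
    )
    return DecodeTrace(times_s=times, probs=probs[0], event_meta=event_meta or {})


@dataclass
class TraceSummary:
    times_s: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: int


def average_traces(
    traces: Sequence[DecodeTrace],
    group_by: str | None = None,
) -> TraceSummary | dict[str, TraceSummary]:
    """Pointwise mean and standard error; optionally grouped by a meta field."""
    if not traces:
        raise ValueError("no traces to average")
    grid = traces[0].times_s
    for tr in traces:
        if len(tr.times_s) != len(grid) or not np.allclose(tr.times_s, grid):
            raise ValueError("traces have mismatched time grids")
    if group_by is not None:
        groups: dict[str, list[DecodeTrace]] = {}
        for tr in traces:
            key = tr.event_meta[group_by]
            groups.setdefault(key, []).append(tr)
        return {k: average_traces(v) for k, v in groups.items()}
    mat = np.stack([tr.probs for tr in traces])
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return TraceSummary(times_s=grid, mean=mean, sem=sem, n=n)
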