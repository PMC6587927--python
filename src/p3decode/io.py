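"""Readers/writers: HDF5 recording container + JSON sidecar, TSV tables, checkpoints."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .decoder import ModelConfig, TrainedDecoder
from .preprocess import EventTable, Recording

EVENT_TSV_COLUMNS = [
    "onset_s", "label", "subject", "experiment", "condition", "rt_s", "fixation_latency_s",
]


def save_recording(rec: Recording, path: str | Path) -> Path:
    """Write an HDF5 container plus a human-readable JSON sidecar."""
    path = Path(path)
    meta = {
        "sample_rate_hz": rec.sample_rate_hz,
        "channel_names": list(rec.channel_names),
        "subject": rec.subject,
        "experiment": rec.experiment,
    }
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=rec.data, compression="gzip", compression_opts=1)
        fh.attrs["meta"] = json.dumps(meta)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))
    return path


def load_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as fh:
        data = fh["data"][()]
        meta = json.loads(fh.attrs["meta"])
    return Recording(
        data=data,
        sample_rate_hz=float(meta["sample_rate_hz"]),
        channel_names=tuple(meta["channel_names"]),
        subject=meta["subject"],
        experiment=meta["experiment"],
    )


def save_events(events: EventTable, path: str | Path) -> Path:
    path = Path(path)
    df = events.df.copy()
    for col in EVENT_TSV_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    cols = EVENT_TSV_COLUMNS + [c for c in df.columns if c not in EVENT_TSV_COLUMNS]
    df[cols].to_csv(path, sep="\t", index=False)
    return path


def load_events(path: str | Path) -> EventTable:
    df = pd.read_csv(path, sep="\t", dtype={"subject": str, "experiment": str, "condition": str})
    return EventTable(df)


def save_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_checkpoint(decoder: TrainedDecoder, path: str | Path) -> Path:
    """Model checkpoint: weights + batch-norm state + config + manifest in HDF5."""
    path = Path(path)
    cfg = {
        "n_channels": decoder.config.n_channels,
        "n_samples": decoder.config.n_samples,
        "n_classes": decoder.config.n_classes,
        "n_temporal_filters": decoder.config.n_temporal_filters,
        "temporal_kernel_len": decoder.config.temporal_kernel_len,
        "depth_multiplier": decoder.config.depth_multiplier,
        "separable_kernel_len": decoder.config.separable_kernel_len,
        "pool1": decoder.config.pool1,
        "pool2": decoder.config.pool2,
        "dropout_p": decoder.config.dropout_p,
    }
    with h5py.File(path, "w") as fh:
        for name, arr in decoder.weights.items():
            fh.create_dataset(f"weights/{name}", data=arr)
        for name, arr in decoder.bn_state.items():
            fh.create_dataset(f"bn_state/{name}", data=arr)
        fh.attrs["config"] = json.dumps(cfg)
        fh.attrs["manifest"] = json.dumps(decoder.training_manifest)
    return path


def load_checkpoint(path: str | Path) -> TrainedDecoder:
    with h5py.File(path, "r") as fh:
        cfg = ModelConfig(**json.loads(fh.attrs["config"]))
        manifest = json.loads(fh.attrs["manifest"])
        weights = {k: fh[f"weights/{k}"][()] for k in fh["weights"]}
        bn_state = {k: fh[f"bn_state/{k}"][()] for k in fh["bn_state"]}
    return TrainedDecoder(cfg, weights, bn_state, manifest)
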