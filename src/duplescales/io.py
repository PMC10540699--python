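"""On-disk formats: BIDS-events-style TSV, HDF5 recordings/epochs, JSON
reports, and the run manifest."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EVENT_COLUMNS, EpochsSet, Recording

EVENTS_REQUIRED = ("onset", "duration", "trial_type", "trial_index", "block",
                   "condition", "scale_index", "position", "f0_hz",
                   "level_db", "role")


def write_events(events: pd.DataFrame, path) -> None:
    """Tab-separated events table, UTF-8, missing values as 'n/a'."""
    events.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    missing = [c for c in EVENTS_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"events file {path} lacks required columns: "
                         f"{missing}")
    return df


def write_recording(recording: Recording, path) -> None:
    """HDF5 layout v1: float32 data, events as column datasets."""
    with h5py.File(path, "w") as f:
        f.attrs["layout_version"] = 1
        f.attrs["sample_rate_hz"] = recording.sample_rate_hz
        if recording.subject is not None:
            f.attrs["subject"] = recording.subject
        f.create_dataset("data", data=recording.data.astype(np.float32),
                         compression="gzip", compression_opts=1)
        f.create_dataset("channel_names",
                         data=np.array(recording.channel_names, dtype="S"))
        f.create_dataset("channel_positions",
                         data=recording.channel_positions.astype(np.float64))
        g = f.create_group("events")
        for col in recording.events.columns:
            vals = recording.events[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            g.create_dataset(col, data=vals)
        if recording.trial_spans is not None:
            s = f.create_group("trial_spans")
            for col in recording.trial_spans.columns:
                s.create_dataset(col, data=recording.trial_spans[col].to_numpy())


def read_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        events = {}
        for col, ds in f["events"].items():
            vals = ds[()]
            if vals.dtype.kind == "S":
                vals = np.array([v.decode() for v in vals])
            events[col] = vals
        spans = None
        if "trial_spans" in f:
            spans = pd.DataFrame({c: ds[()] for c, ds in
                                  f["trial_spans"].items()})
        return Recording(
            data=f["data"][()],
            sample_rate_hz=float(f.attrs["sample_rate_hz"]),
            channel_names=[n.decode() for n in f["channel_names"][()]],
            channel_positions=f["channel_positions"][()],
            events=pd.DataFrame(events),
            trial_spans=spans,
            subject=int(f.attrs["subject"]) if "subject" in f.attrs else None,
        )


def write_epochs(epochs: EpochsSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["layout_version"] = 1
        f.attrs["sample_rate_hz"] = epochs.sample_rate_hz
        f.create_dataset("data", data=epochs.data.astype(np.float32),
                         compression="gzip", compression_opts=1)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("channel_names",
                         data=np.array(epochs.channel_names, dtype="S"))
        f.create_dataset("channel_positions", data=epochs.channel_positions)
        g = f.create_group("labels")
        for col in epochs.labels.columns:
            vals = epochs.labels[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            g.create_dataset(col, data=vals)


def read_epochs(path) -> EpochsSet:
    with h5py.File(path, "r") as f:
        labels = {}
        for col, ds in f["labels"].items():
            vals = ds[()]
            if vals.dtype.kind == "S":
                vals = np.array([v.decode() for v in vals])
            labels[col] = vals
        return EpochsSet(
            data=f["data"][()].astype(np.float64),
            times=f["times"][()],
            labels=pd.DataFrame(labels),
            sample_rate_hz=float(f.attrs["sample_rate_hz"]),
            channel_names=[n.decode() for n in f["channel_names"][()]],
            channel_positions=f["channel_positions"][()],
        )


class _JSONEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_JSONEncoder,
                                     allow_nan=True) + "\n")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, config_dict: dict, files: list[str]) -> None:
    out_dir = Path(out_dir)
    cfg_hash = hashlib.sha256(
        json.dumps(config_dict, sort_keys=True, cls=_JSONEncoder).encode()
    ).hexdigest()
    manifest = {
        "config_hash": cfg_hash,
        "config": config_dict,
        "checksums": {f: sha256_of(out_dir / f) for f in files
                      if (out_dir / f).exists()},
    }
    write_json(manifest, out_dir / "manifest.json")
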