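"""Readers and writers for the on-disk formats used between pipeline stages.

Recordings are stored as raw little-endian binary (int16 with a scale
factor, or float32) plus a JSON sidecar carrying the sampling rate,
channel count, dtype and scale.  Spikes go to HDF5 (or CSV), features and
labels to CSV, codebooks and reports to JSON.  All sample indices in
files are 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "RawRecording",
    "write_recording",
    "read_recording",
    "write_truth",
    "read_truth",
    "write_spikes",
    "read_spikes",
    "write_features",
    "read_features",
    "write_codebook_json",
    "read_codebook_json",
    "write_labels",
    "read_labels",
    "write_report",
    "read_report",
]

_INT16_MAX = 32767


@dataclass
class RawRecording:
    """A multi-channel sample matrix (channels x samples) plus metadata."""

    samples: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


def write_recording(rec: RawRecording, path, meta_path=None, dtype="float32",
                    scale: float | None = None) -> None:
    """Write raw binary samples plus a JSON sidecar.

    ``dtype='int16'`` quantizes as ``round(x * scale)`` (scale defaults to
    the largest value that keeps the data in range); values that would
    overflow int16 raise instead of clipping silently.
    """
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else path.with_suffix(".json")
    if dtype == "float32":
        data = rec.samples.astype("<f4")
        scale = 1.0
    elif dtype == "int16":
        if scale is None:
            amax = np.max(np.abs(rec.samples))
            scale = _INT16_MAX / amax if amax > 0 else 1.0
        scaled = np.round(rec.samples * scale)
        if np.any(np.abs(scaled) > _INT16_MAX):
            raise ValueError(
                "int16 overflow on write: samples * scale exceed "
                f"+-{_INT16_MAX}; reduce scale"
            )
        data = scaled.astype("<i2")
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    data.tofile(path)
    meta = {
        "sampling_rate_hz": rec.sampling_rate_hz,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "dtype": dtype,
        "scale": float(scale),
        "byte_order": "little",
        "index_origin": 0,
    }
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_recording(path, meta_path=None) -> RawRecording:
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else path.with_suffix(".json")
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("sampling_rate_hz", "n_channels", "n_samples", "dtype",
                "scale"):
        if key not in meta:
            raise ValueError(f"metadata field {key!r} missing in {meta_path}")
    np_dtype = {"float32": "<f4", "int16": "<i2"}[meta["dtype"]]
    raw = np.fromfile(path, dtype=np_dtype)
    expected = meta["n_channels"] * meta["n_samples"]
    if raw.size != expected:
        raise ValueError(
            f"truncated or oversized recording {path}: got {raw.size} "
            f"samples ({raw.size * raw.itemsize} bytes), metadata implies "
            f"{expected} ({expected * raw.itemsize} bytes)"
        )
    samples = raw.astype(float).reshape(meta["n_channels"],
                                        meta["n_samples"]) / meta["scale"]
    return RawRecording(samples=samples,
                        sampling_rate_hz=meta["sampling_rate_hz"])


def write_truth(truth, path) -> None:
    truth.events.to_csv(path, index=False)


def read_truth(path):
    from .synth import GroundTruth

    df = pd.read_csv(path)
    missing = {"channel", "sample_index", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"ground-truth CSV missing columns {sorted(missing)}")
    return GroundTruth(df)


# ---------------------------------------------------------------------------
# Detected spikes
# ---------------------------------------------------------------------------

def write_spikes(spikes, path) -> None:
    """Write detected spikes to HDF5 (.h5/.hdf5) or CSV.

    HDF5 layout: datasets ``channel``, ``trigger_index``, ``peak_index``
    (ints) and ``waveforms`` (n_spikes x m floats).  The CSV dialect puts
    the waveform samples in columns ``s0..s{m-1}``.
    """
    path = Path(path)
    channel = np.array([s.channel for s in spikes], dtype=np.int64)
    trig = np.array([s.trigger_index for s in spikes], dtype=np.int64)
    peak = np.array([s.peak_index for s in spikes], dtype=np.int64)
    wf = (np.vstack([s.waveform for s in spikes])
          if spikes else np.empty((0, 0)))
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("channel", data=channel)
            f.create_dataset("trigger_index", data=trig)
            f.create_dataset("peak_index", data=peak)
            f.create_dataset("waveforms", data=wf)
    else:
        df = pd.DataFrame({"channel": channel, "trigger_index": trig,
                           "peak_index": peak})
        for i in range(wf.shape[1]):
            df[f"s{i}"] = wf[:, i]
        df.to_csv(path, index=False)


def read_spikes(path):
    from .detection import DetectedSpike

    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            channel = f["channel"][:]
            trig = f["trigger_index"][:]
            peak = f["peak_index"][:]
            wf = f["waveforms"][:]
    else:
        df = pd.read_csv(path)
        required = {"channel", "trigger_index", "peak_index"}
        if not required <= set(df.columns):
            raise ValueError(
                f"spike CSV missing columns {sorted(required - set(df.columns))}"
            )
        channel = df["channel"].to_numpy()
        trig = df["trigger_index"].to_numpy()
        peak = df["peak_index"].to_numpy()
        scols = [c for c in df.columns if c.startswith("s")
                 and c[1:].isdigit()]
        scols.sort(key=lambda c: int(c[1:]))
        wf = df[scols].to_numpy(dtype=float)
    return [DetectedSpike(channel=int(q), waveform=w, trigger_index=int(t),
                          peak_index=int(p))
            for q, w, t, p in zip(channel, wf, trig, peak)]


# ---------------------------------------------------------------------------
# Features / labels / codebooks / reports
# ---------------------------------------------------------------------------

def write_features(channels, values, path, extractor_tag="PDAC",
                   sidecar_path=None) -> None:
    values = np.atleast_2d(values)
    df = pd.DataFrame({"channel": np.asarray(channels, dtype=int)})
    for i in range(values.shape[1]):
        df[f"f{i + 1}"] = values[:, i]
    df.to_csv(path, index=False)
    sidecar = Path(sidecar_path) if sidecar_path else Path(path).with_suffix(
        ".json")
    sidecar.write_text(json.dumps({"extractor": extractor_tag,
                                   "n_features": int(values.shape[1])},
                                  indent=2, sort_keys=True))


def read_features(path):
    df = pd.read_csv(path)
    if "channel" not in df.columns or "f1" not in df.columns:
        raise ValueError(
            "features CSV must have a header with 'channel' and 'f1...' "
            f"columns; got {list(df.columns)}"
        )
    fcols = sorted((c for c in df.columns if c.startswith("f")
                    and c[1:].isdigit()), key=lambda c: int(c[1:]))
    return df["channel"].to_numpy(dtype=int), df[fcols].to_numpy(dtype=float)


def write_codebook_json(codebook, path) -> None:
    obj = {
        "eta": codebook.eta,
        "eta_exponent": codebook.eta_exponent,
        "channels": {str(q): c.tolist()
                     for q, c in codebook.centers.items()},
        "update_count": {str(q): int(n)
                         for q, n in codebook.update_count.items()},
    }
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def read_codebook_json(path):
    from .clustering import Codebook

    obj = json.loads(Path(path).read_text())
    cb = Codebook(eta=obj["eta"], eta_exponent=obj.get("eta_exponent"))
    for q, centers in obj["channels"].items():
        cb.centers[int(q)] = np.asarray(centers, dtype=float)
        cb.update_count[int(q)] = int(obj.get("update_count", {}).get(q, 0))
    return cb


def write_labels(channels, spike_indices, labels, path) -> None:
    pd.DataFrame({"channel": np.asarray(channels, dtype=int),
                  "spike_index": np.asarray(spike_indices, dtype=int),
                  "label": np.asarray(labels, dtype=int)}
                 ).to_csv(path, index=False)


def read_labels(path):
    df = pd.read_csv(path)
    missing = {"channel", "spike_index", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"labels CSV missing columns {sorted(missing)}")
    return (df["channel"].to_numpy(dtype=int),
            df["spike_index"].to_numpy(dtype=int),
            df["label"].to_numpy(dtype=int))


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True,
                                     default=float))


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
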