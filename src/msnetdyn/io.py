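"""Recording container and HDF5 / JSON serialization."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np


@dataclass
class EEGRecording:
    """Multichannel EEG segment.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Potentials in microvolts.
    fs : float
        Sampling rate in Hz.
    channels : list of str
        Channel labels, one per signal row.
    group : str
        Cohort tag (e.g. ``"HC"`` or ``"SZ"``); empty for ungrouped data.
    subject_id : str
    """

    signal: np.ndarray
    fs: float
    channels: list = field(default_factory=list)
    group: str = ""
    subject_id: str = ""

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channels:
            self.channels = [f"ch{i:02d}" for i in range(self.signal.shape[0])]
        if len(self.channels) != self.signal.shape[0]:
            raise ValueError("channel list length does not match signal rows")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, **kwargs) -> "EEGRecording":
        return replace(self, **kwargs)


def save_recording(rec: EEGRecording, path) -> None:
    """Write a recording to HDF5 (datasets /signal, /fs, /channels, /group)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal)
        f.create_dataset("fs", data=rec.fs)
        f.create_dataset("channels", data=np.array(rec.channels, dtype="S"))
        f.create_dataset("group", data=np.bytes_(rec.group))
        f.create_dataset("subject_id", data=np.bytes_(rec.subject_id))


def load_recording(path) -> EEGRecording:
    import h5py

    with h5py.File(path, "r") as f:
        return EEGRecording(
            signal=f["signal"][()],
            fs=float(f["fs"][()]),
            channels=[c.decode() for c in f["channels"][()]],
            group=bytes(f["group"][()]).decode(),
            subject_id=bytes(f["subject_id"][()]).decode(),
        )


def run_length_encode(labels) -> list:
    """RLE of an integer label sequence as [[value, count], ...]."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [[int(labels[s]), int(e - s)] for s, e in zip(starts, ends)]


def run_length_decode(rle) -> np.ndarray:
    if not rle:
        return np.array([], dtype=int)
    return np.concatenate([np.full(n, v, dtype=int) for v, n in rle])


def save_ground_truth(gt, path) -> None:
    """Ground-truth sidecar JSON: templates, RLE labels, coupling, group."""
    payload = {
        "templates": np.asarray(gt.templates).tolist(),
        "labels_rle": run_length_encode(gt.labels),
        "coupling_used": {str(k): np.asarray(v).tolist() for k, v in gt.coupling_used.items()},
        "group": gt.group,
    }
    Path(path).write_text(json.dumps(payload))
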