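"""Shared containers for epoched EEG and raw recordings.

Conventions
-----------
* amplitudes are in microvolts (uV), times in milliseconds, frequencies in Hz;
* epoch arrays are ``(n_trials, n_channels, n_samples)``;
* raw (continuous) arrays are ``(n_channels, n_samples)``;
* trial labels are strings from ``{"self", "familiar", "stranger", "blank"}``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import h5py
import numpy as np

#: 16-channel frontal/central-heavy montage (10-20 names) used throughout.
CHANNELS_16 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T7",
    "C3", "Cz", "C4", "T8", "P3", "Pz", "P4", "Oz",
)

CLASSES = ("self", "familiar", "stranger", "blank")
NAME_CLASSES = ("self", "familiar", "stranger")


@dataclass
class RawRecording:
    """Continuous multichannel EEG with event markers.

    ``marker_samples[i]`` is the stimulus-onset sample index of event *i* and
    ``marker_labels[i]`` its class label.
    """

    data: np.ndarray            # (n_channels, n_samples), uV
    fs: float                   # Hz
    channels: tuple[str, ...] = CHANNELS_16
    marker_samples: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    marker_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raw data must be (n_channels, n_samples)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel list does not match data")
        self.marker_samples = np.asarray(self.marker_samples, dtype=int)
        if len(self.marker_labels) != self.marker_samples.size:
            raise ValueError("marker labels/samples length mismatch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, **kw) -> "RawRecording":
        return dataclasses.replace(self, **kw)


@dataclass
class EpochSet:
    """Trials x channels x samples with per-trial labels and a ms time axis."""

    data: np.ndarray            # (n_trials, n_channels, n_samples), uV
    labels: np.ndarray          # (n_trials,) of str
    times: np.ndarray           # (n_samples,) ms, contains 0
    fs: float
    channels: tuple[str, ...] = CHANNELS_16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (n_trials, n_channels, n_samples)")
        if self.data.shape[0] != self.labels.shape[0]:
            raise ValueError("labels do not match trial count")
        if self.data.shape[2] != self.times.shape[0]:
            raise ValueError("time axis does not match sample count")
        if self.data.shape[0] and not np.any(self.times == 0):
            raise ValueError("time axis must contain 0 ms (stimulus onset)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def select(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(self.data[mask], self.labels[mask], self.times,
                        self.fs, self.channels)

    def class_trials(self, label: str) -> "EpochSet":
        return self.select(self.labels == label)


def save_epochs(path, epochs: EpochSet) -> None:
    """Write an :class:`EpochSet` to an HDF5 archive
    (``/epochs``, ``/labels``, ``/times``, ``/channels``, ``/fs``)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epochs.data)
        f.create_dataset("labels", data=np.asarray(epochs.labels, dtype="S"))
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("channels", data=np.asarray(epochs.channels, dtype="S"))
        f.attrs["fs"] = epochs.fs


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["epochs"][()],
            labels=np.array([s.decode() for s in f["labels"][()]], dtype=object),
            times=f["times"][()],
            fs=float(f.attrs["fs"]),
            channels=tuple(s.decode() for s in f["channels"][()]),
        )


def save_raw(path, raw: RawRecording) -> None:
    """Write a continuous recording + markers to HDF5 (lossless float64)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=raw.data)
        f.create_dataset("marker_samples", data=raw.marker_samples)
        f.create_dataset("marker_labels",
                         data=np.asarray(raw.marker_labels, dtype="S"))
        f.create_dataset("channels", data=np.asarray(raw.channels, dtype="S"))
        f.attrs["fs"] = raw.fs


def load_raw(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        return RawRecording(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            channels=tuple(s.decode() for s in f["channels"][()]),
            marker_samples=f["marker_samples"][()],
            marker_labels=tuple(s.decode() for s in f["marker_labels"][()]),
        )
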