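"""Multichannel biosignal containers.

A :class:`SignalRecord` holds a channels x samples array at a fixed sampling
rate together with per-channel metadata (label, role, units) and an
append-only processing history.  Channel *roles* drive all downstream
processing: ``eeg`` (monopolar scalp channels), ``eeg-bipolar`` (derived
differential montages such as C3-F3), ``emg`` (raw surface EMG),
``emg-rectified`` / ``emg-demodulated`` (derived EMG representations) and
``footswitch`` (0/1 contact signals used for gait event detection).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

#: Channel roles understood by the pipeline.
ROLES = frozenset(
    {
        "eeg",
        "eeg-bipolar",
        "emg",
        "emg-rectified",
        "emg-demodulated",
        "footswitch",
        "other",
    }
)

#: The 10-electrode montage (10-20 system) used for ambulatory recordings.
EEG_1020_LABELS = ("P3", "P4", "C3", "Cz", "C4", "F7", "F3", "Fz", "F4", "F8")


@dataclass
class Channel:
    """Metadata for one channel of a :class:`SignalRecord`."""

    label: str
    role: str
    units: str = "uV"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown channel role {self.role!r}; expected one of {sorted(ROLES)}")

    def copy(self) -> "Channel":
        return Channel(self.label, self.role, self.units, copy.deepcopy(self.extra))


@dataclass
class SignalRecord:
    """Raw or conditioned multichannel time series.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``.
    sample_rate_hz
        Sampling rate shared by all channels.
    channels
        One :class:`Channel` per row of ``data``.
    history
        Ordered, append-only list of processing step descriptors.
    meta
        Free-form record metadata (participant id, group, condition,
        walking speed, ...). Treated as opaque by the pipeline.
    """

    data: np.ndarray
    sample_rate_hz: float
    channels: list[Channel]
    history: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel descriptors for {self.data.shape[0]} data rows"
            )
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")

    # -- basic queries ----------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz

    def index(self, label: str) -> int:
        for i, c in enumerate(self.channels):
            if c.label == label:
                return i
        raise KeyError(f"channel {label!r} not found; available: {self.labels}")

    def get(self, label: str) -> np.ndarray:
        """Return the (view of the) sample vector of one channel."""
        return self.data[self.index(label)]

    def channel(self, label: str) -> Channel:
        return self.channels[self.index(label)]

    def pick(self, *roles: str) -> list[int]:
        """Indices of all channels whose role is in ``roles``."""
        return [i for i, c in enumerate(self.channels) if c.role in roles]

    # -- mutation helpers -------------------------------------------------
    def copy(self) -> "SignalRecord":
        return SignalRecord(
            self.data.copy(),
            self.sample_rate_hz,
            [c.copy() for c in self.channels],
            list(self.history),
            copy.deepcopy(self.meta),
        )

    def log(self, message: str) -> None:
        """Append a step descriptor to the processing history."""
        self.history.append(message)

    def append_channel(self, samples: np.ndarray, channel: Channel) -> None:
        samples = np.asarray(samples, dtype=float)
        if samples.shape != (self.n_samples,):
            raise ValueError("appended channel length must match the record")
        if channel.label in self.labels:
            raise ValueError(f"channel {channel.label!r} already exists")
        self.data = np.vstack([self.data, samples[None, :]])
        self.channels.append(channel)
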