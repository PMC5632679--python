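"""In-memory containers for continuous recordings and epoched data.

``Recording`` holds a continuous multichannel signal in microvolts with
class-labelled event markers; ``EpochSet`` holds the trials × channels ×
samples array produced by segmentation, together with the provenance of
every rejection step applied to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

#: The three processing levels of the paradigm: non-target (no processing),
#: shallow target (colour match, count only), deep target (full task).
CLASSES = ("NT", "ST", "DT")


class InvalidConfigurationError(ValueError):
    """A parameter combination violates an operation's contract."""


class MissingClassError(ValueError):
    """An operation requiring both classes of a pair saw only one."""


class DegenerateDataError(ValueError):
    """A cleaning step would remove every channel or every epoch."""


@dataclass
class Recording:
    """Continuous multichannel EEG in μV with event markers.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    channel_labels : list of str
        Unique 10-20 channel names (may include ``EOG``).
    fs : float
        Sampling rate in Hz.
    events : list of (int, str)
        ``(sample_index, class_label)`` stimulus onsets.
    annotations : list of dict
        Ground-truth bookkeeping (e.g. injected artifacts); free-form.
    """

    data: np.ndarray
    channel_labels: list[str]
    fs: float
    events: list[tuple[int, str]] = field(default_factory=list)
    annotations: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidConfigurationError("data must be 2-D (channels × samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise InvalidConfigurationError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise InvalidConfigurationError("channel labels must be unique")
        if self.fs <= 0:
            raise InvalidConfigurationError("sampling rate must be positive")
        n = self.data.shape[1]
        for idx, label in self.events:
            if not 0 <= idx < n:
                raise InvalidConfigurationError(f"event at sample {idx} outside data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise InvalidConfigurationError(f"channel {label!r} not present") from None

    def copy(self) -> "Recording":
        return Recording(
            data=self.data.copy(),
            channel_labels=list(self.channel_labels),
            fs=self.fs,
            events=list(self.events),
            annotations=[dict(a) for a in self.annotations],
        )


@dataclass
class EpochSet:
    """Trials × channels × samples array with labels and rejection provenance.

    ``times`` is in milliseconds relative to stimulus onset.  Every channel or
    epoch rejection appends a record to ``rejection_log`` so the surviving
    index mapping can be reconstructed exactly.
    """

    data: np.ndarray
    labels: np.ndarray
    times: np.ndarray
    fs: float
    channel_labels: list[str]
    rejection_log: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise InvalidConfigurationError("data must be 3-D (trials × channels × samples)")
        if len(self.labels) != self.data.shape[0]:
            raise InvalidConfigurationError("labels length must equal trial count")
        if len(self.times) != self.data.shape[2]:
            raise InvalidConfigurationError("time axis length must equal sample count")
        if len(self.channel_labels) != self.data.shape[1]:
            raise InvalidConfigurationError("channel label count must equal channel count")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidConfigurationError("time axis must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise InvalidConfigurationError(f"channel {label!r} not present") from None

    def time_mask(self, start_ms: float, end_ms: float) -> np.ndarray:
        """Boolean mask over samples for the half-open window [start, end) ms."""
        return (self.times >= start_ms) & (self.times < end_ms)

    def select_classes(self, classes: tuple[str, ...]) -> "EpochSet":
        mask = np.isin(self.labels, classes)
        return replace(
            self,
            data=self.data[mask],
            labels=self.labels[mask],
            rejection_log=list(self.rejection_log),
        )

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            labels=self.labels.copy(),
            times=self.times.copy(),
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            rejection_log=[dict(r) for r in self.rejection_log],
        )
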