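"""Core in-memory containers for oddball MEG data.

All sensor data are planar-gradiometer signals in fT/cm, stored as
``(n_channels, n_samples)`` float arrays. Event onsets are integer sample
indices into the continuous recording; labels are ``"standard"`` or
``"deviant"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

STANDARD = "standard"
DEVIANT = "deviant"
_LABELS = (STANDARD, DEVIANT)


@dataclass
class RawRecording:
    """Continuous multichannel recording with an event table.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Sensor signals in fT/cm.
    fs_hz : float
        Sampling rate.
    onsets : ndarray of int
        Event onset samples, ascending.
    labels : ndarray of str
        Condition label per event (``standard`` / ``deviant``).
    channel_ids : ndarray of str
        One id per channel.
    positions : ndarray, shape (n_channels, 2)
        2-D sensor layout positions (arbitrary planar units).
    """

    data: np.ndarray
    fs_hz: float
    onsets: np.ndarray
    labels: np.ndarray
    channel_ids: np.ndarray = None
    positions: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite values")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        self.onsets = np.asarray(self.onsets, dtype=int)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.onsets.shape != self.labels.shape:
            raise ValueError("onsets and labels must have equal length")
        bad = set(self.labels) - set(_LABELS)
        if bad:
            raise ValueError(f"unknown event labels: {sorted(bad)}")
        n_ch = self.data.shape[0]
        if self.channel_ids is None:
            self.channel_ids = np.array([f"CH{i:03d}" for i in range(n_ch)],
                                        dtype=object)
        else:
            self.channel_ids = np.asarray(self.channel_ids, dtype=object)
            if len(self.channel_ids) != n_ch:
                raise ValueError("channel_ids length mismatch")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (n_ch, 2):
                raise ValueError("positions must be (n_channels, 2)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def copy(self) -> "RawRecording":
        return RawRecording(self.data.copy(), self.fs_hz,
                            self.onsets.copy(), self.labels.copy(),
                            self.channel_ids.copy(),
                            None if self.positions is None
                            else self.positions.copy())


@dataclass
class EpochSet:
    """Epoch x channel x time tensor with condition labels.

    The within-epoch time axis runs from ``tmin_ms`` to ``tmax_ms`` relative
    to stimulus onset; sample 0 corresponds to ``tmin_ms``.
    """

    data: np.ndarray
    labels: np.ndarray
    fs_hz: float
    tmin_ms: float = -100.0
    tmax_ms: float = 500.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (epoch, channel, time)")
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per epoch required")
        n_expected = int(round((self.tmax_ms - self.tmin_ms)
                               * self.fs_hz / 1000.0))
        if self.data.shape[2] != n_expected:
            raise ValueError(
                f"epoch length {self.data.shape[2]} != "
                f"round((tmax-tmin)*fs/1000) = {n_expected}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Within-epoch time axis in ms (onset at 0)."""
        return self.tmin_ms + np.arange(self.n_times) * 1000.0 / self.fs_hz

    def select(self, label: str) -> "EpochSet":
        """Return the sub-set of epochs carrying ``label``."""
        mask = self.labels == label
        if not mask.any():
            raise ValueError(f"no epochs labelled {label!r}")
        return replace(self, data=self.data[mask], labels=self.labels[mask])


@dataclass
class Erf:
    """Event-related field: a channel x time average with provenance."""

    data: np.ndarray
    times_ms: np.ndarray
    condition: str  # standard | deviant | difference | weighted
    n_epochs: int = 0
    parent_n_epochs: tuple = ()

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Erf data must be 2-D (channel x time)")
        if self.data.shape[1] != len(self.times_ms):
            raise ValueError("time axis length mismatch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class WindowSpec:
    """Rectangular weighting window on the MMR time range.

    Within-epoch time ``m`` is measured from stimulus onset; samples with
    ``n1_ms <= m <= n2_ms`` get ``inside_weight`` and all others (including
    the whole pre-stimulus segment) get ``outside_weight``.
    """

    n1_ms: float = 96.0
    n2_ms: float = 276.0
    inside_weight: float = 1.0
    outside_weight: float = 0.2

    def __post_init__(self):
        if not self.n1_ms < self.n2_ms:
            raise ValueError("window requires n1 < n2")
        if self.inside_weight < 0 or self.outside_weight < 0:
            raise ValueError("window weights must be non-negative")

    def weights(self, times_ms: np.ndarray) -> np.ndarray:
        """Per-sample gain for a within-epoch time axis in ms."""
        t = np.asarray(times_ms, dtype=float)
        inside = (t >= self.n1_ms) & (t <= self.n2_ms)
        return np.where(inside, self.inside_weight, self.outside_weight)
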