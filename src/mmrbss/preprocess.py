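"""Epoch segmentation, artifact rejection, averaging, and the two
approaches' data preparation: the subtraction baseline (deviant ERF minus
standard ERF) and the weighted path (deviant concatenation followed by
rectangular-window weighting of the MMR time range)."""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from scipy import signal as _sig

from .containers import DEVIANT, STANDARD, EpochSet, Erf, RawRecording, WindowSpec

logger = logging.getLogger(__name__)

__all__ = [
    "segment", "reject", "lowpass", "average", "subtract_erf",
    "concatenate_deviants", "apply_window", "baseline_correct",
]


def segment(raw: RawRecording, tmin_ms: float = -100.0,
            tmax_ms: float = 500.0) -> EpochSet:
    """Cut one epoch per event from the continuous recording.

    Events whose epoch would extend past a recording edge are dropped with
    a warning; an empty usable set is an error.
    """
    fs = raw.fs_hz
    start_off = int(round(tmin_ms * fs / 1000.0))
    n_t = int(round((tmax_ms - tmin_ms) * fs / 1000.0))
    epochs, labels, dropped = [], [], 0
    for onset, label in zip(raw.onsets, raw.labels):
        s0 = onset + start_off
        if s0 < 0 or s0 + n_t > raw.n_samples:
            dropped += 1
            continue
        epochs.append(raw.data[:, s0:s0 + n_t])
        labels.append(label)
    if dropped:
        logger.warning("segment: dropped %d event(s) too close to a "
                       "recording edge", dropped)
    if not epochs:
        raise ValueError("no usable events within the recording")
    return EpochSet(data=np.stack(epochs), labels=np.array(labels,
                                                           dtype=object),
                    fs_hz=fs, tmin_ms=tmin_ms, tmax_ms=tmax_ms)


def reject(epochs: EpochSet, threshold_ftcm: float = 4000.0,
           mode: str = "peak_to_peak") -> EpochSet:
    """Drop epochs exceeding an amplitude threshold on any channel.

    The default criterion is the per-channel peak-to-peak range within the
    epoch (the conventional reading of an fT/cm rejection limit on planar
    gradiometers); ``mode="absolute"`` uses the absolute peak instead.
    """
    if threshold_ftcm <= 0:
        raise ValueError("rejection threshold must be positive")
    if mode == "peak_to_peak":
        extent = epochs.data.max(axis=2) - epochs.data.min(axis=2)
    elif mode == "absolute":
        extent = np.abs(epochs.data).max(axis=2)
    else:
        raise ValueError(f"unknown rejection mode {mode!r}")
    keep = ~(extent > threshold_ftcm).any(axis=1)
    n_rej = int((~keep).sum())
    if n_rej:
        logger.info("reject: removed %d of %d epochs (> %g fT/cm)",
                    n_rej, epochs.n_epochs, threshold_ftcm)
    if not keep.any():
        raise ValueError("all epochs exceeded the rejection threshold")
    return replace(epochs, data=epochs.data[keep], labels=epochs.labels[keep])


def lowpass(data: np.ndarray, fs_hz: float, cutoff_hz: float = 30.0,
            order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the last axis."""
    if not 0 < cutoff_hz < fs_hz / 2.0:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    sos = _sig.butter(order, cutoff_hz, btype="low", fs=fs_hz, output="sos")
    return _sig.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract the pre-stimulus mean per epoch and channel (optional;
    not part of the default pipeline)."""
    pre = epochs.times_ms < 0
    if not pre.any():
        raise ValueError("no pre-stimulus samples to baseline on")
    base = epochs.data[:, :, pre].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - base)


def average(epochs: EpochSet, condition: str) -> Erf:
    """Arithmetic mean over the epochs of one condition."""
    sub = epochs.select(condition)
    return Erf(data=sub.data.mean(axis=0), times_ms=epochs.times_ms,
               condition=condition, n_epochs=sub.n_epochs)


def subtract_erf(dev: Erf, std: Erf) -> Erf:
    """Difference waveform: deviant ERF minus standard ERF."""
    if dev.data.shape != std.data.shape or not np.array_equal(
            dev.times_ms, std.times_ms):
        raise ValueError("ERFs must share channel and time axes")
    return Erf(data=dev.data - std.data, times_ms=dev.times_ms,
               condition="difference",
               parent_n_epochs=(dev.n_epochs, std.n_epochs))


def concatenate_deviants(epochs: EpochSet) -> RawRecording:
    """Place the deviant epochs end-to-end as new periodic raw data.

    Deviant epochs keep their original temporal order; the output period is
    one epoch length, with a synthetic event at each epoch start (label
    ``deviant``, onset at the epoch's stimulus-onset sample).
    """
    mask = epochs.labels == DEVIANT
    if mask.sum() < 2:
        raise ValueError("need at least 2 deviant epochs to concatenate")
    dev = epochs.data[mask]                       # (n_dev, n_ch, n_t)
    n_dev, n_ch, n_t = dev.shape
    data = dev.transpose(1, 0, 2).reshape(n_ch, n_dev * n_t)
    onset_in_epoch = int(round(-epochs.tmin_ms * epochs.fs_hz / 1000.0))
    onsets = n_t * np.arange(n_dev) + onset_in_epoch
    labels = np.array([DEVIANT] * n_dev, dtype=object)
    return RawRecording(data=data, fs_hz=epochs.fs_hz, onsets=onsets,
                        labels=labels)


def apply_window(concatenated: RawRecording, window: WindowSpec,
                 epoch_len: int = None, tmin_ms: float = -100.0
                 ) -> RawRecording:
    """Repeat the rectangular MMR window over the concatenated epochs.

    Every sample whose within-epoch time ``m`` (measured from stimulus
    onset) falls in ``[n1, n2]`` is multiplied by ``inside_weight``; all
    other samples — including the pre-stimulus segment — by
    ``outside_weight``.
    """
    n_samples = concatenated.n_samples
    if epoch_len is None:
        if len(concatenated.onsets) < 2:
            raise ValueError("cannot infer epoch length from fewer "
                             "than 2 events")
        epoch_len = int(concatenated.onsets[1] - concatenated.onsets[0])
    if n_samples % epoch_len:
        raise ValueError("concatenated length is not a whole number "
                         "of epochs")
    times_ms = tmin_ms + np.arange(epoch_len) * 1000.0 / concatenated.fs_hz
    if window.n1_ms < times_ms[0] or window.n2_ms > times_ms[-1]:
        raise ValueError("window does not fit within the epoch time axis")
    gain = window.weights(times_ms)
    data = concatenated.data * np.tile(gain, n_samples // epoch_len)
    return RawRecording(data=data, fs_hz=concatenated.fs_hz,
                        onsets=concatenated.onsets.copy(),
                        labels=concatenated.labels.copy(),
                        channel_ids=concatenated.channel_ids.copy(),
                        positions=None if concatenated.positions is None
                        else concatenated.positions.copy())
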