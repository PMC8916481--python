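"""File I/O: HDF5 container, CSV + JSON sidecar, optional FIF reading.

The package's native container is a single HDF5 file holding the sensor
matrix in fT/cm, the sampling rate, the event table, the channel layout,
and (for simulated data) a parallel ground-truth group.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import numpy as np

from .containers import RawRecording
from .decompose import ConvergenceRecord, Decomposition, DelaySchedule
from .simulate import GroundTruth

logger = logging.getLogger(__name__)

__all__ = ["write_recording", "read_recording", "write_decomposition",
           "read_decomposition"]

_STR = h5py.string_dtype(encoding="utf-8")


def write_recording(path, raw: RawRecording, truth: GroundTruth = None):
    """Write a recording (and optional ground truth) to the HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=raw.data)
        f["data"].attrs["units"] = "fT/cm"
        f.attrs["fs_hz"] = raw.fs_hz
        ev = f.create_group("events")
        ev.create_dataset("onset", data=raw.onsets)
        ev.create_dataset("label", data=[str(x) for x in raw.labels],
                          dtype=_STR)
        ch = f.create_group("channels")
        ch.create_dataset("id", data=[str(x) for x in raw.channel_ids],
                          dtype=_STR)
        if raw.positions is not None:
            ch.create_dataset("pos", data=raw.positions)
        if truth is not None:
            gt = f.create_group("ground_truth")
            gt.create_dataset("true_mixing", data=truth.true_mixing)
            gt.create_dataset("true_sources", data=truth.true_sources)
            gt.attrs["mmr_source_index"] = truth.mmr_source_index
            gt.attrs["mmr_window_ms"] = truth.mmr_window_ms


def _read_hdf5(path, with_truth=False):
    with h5py.File(path, "r") as f:
        if "events" not in f:
            raise ValueError(f"{path}: container has no event table")
        raw = RawRecording(
            data=f["data"][()], fs_hz=float(f.attrs["fs_hz"]),
            onsets=f["events/onset"][()],
            labels=f["events/label"].asstr()[()],
            channel_ids=f["channels/id"].asstr()[()],
            positions=f["channels/pos"][()] if "channels/pos" in f
            else None)
        truth = None
        if with_truth and "ground_truth" in f:
            gt = f["ground_truth"]
            truth = GroundTruth(
                onsets=raw.onsets, labels=raw.labels,
                true_mixing=gt["true_mixing"][()],
                true_sources=gt["true_sources"][()],
                mmr_source_index=int(gt.attrs["mmr_source_index"]),
                mmr_window_ms=tuple(gt.attrs["mmr_window_ms"]))
    return (raw, truth) if with_truth else raw


def _read_csv(path):
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"CSV recording {path} requires the JSON sidecar {sidecar} "
            "(fs_hz, events, channels)")
    meta = json.loads(sidecar.read_text())
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    events = meta.get("events")
    if not events:
        raise ValueError(f"{sidecar}: no events listed")
    onsets = [e[0] for e in events]
    labels = [e[1] for e in events]
    return RawRecording(
        data=data, fs_hz=float(meta["fs_hz"]), onsets=onsets, labels=labels,
        channel_ids=np.asarray(meta["channel_ids"], dtype=object)
        if "channel_ids" in meta else None,
        positions=np.asarray(meta["positions"], dtype=float)
        if "positions" in meta else None)


def _read_fif(path):
    try:
        import mne
    except ImportError as err:
        raise ImportError(
            "reading FIF files requires the optional dependency 'mne' "
            "(pip install mne)") from err
    raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
    picks = mne.pick_types(raw.info, meg="grad")
    if picks.size == 0:
        raise ValueError(f"{path}: no planar gradiometer channels")
    data = raw.get_data(picks=picks) * 1e13  # T/m -> fT/cm
    try:
        events = mne.find_events(raw, verbose="error")
    except ValueError as err:
        raise ValueError(f"{path}: no event/stim information "
                         "found") from err
    onsets = events[:, 0] - raw.first_samp
    # convention: trigger value 1 = standard, anything else = deviant
    labels = np.where(events[:, 2] == 1, "standard", "deviant")
    names = [raw.ch_names[p] for p in picks]
    pos = np.array([raw.info["chs"][p]["loc"][:2] for p in picks])
    return RawRecording(data=data, fs_hz=float(raw.info["sfreq"]),
                        onsets=onsets, labels=labels,
                        channel_ids=np.asarray(names, dtype=object),
                        positions=pos)


def read_recording(path, format: str = None, with_truth: bool = False):
    """Read a recording from HDF5, CSV (+ JSON sidecar), or FIF.

    ``format`` in {"hdf5", "csv", "fif"}; inferred from the extension
    when omitted. ``with_truth=True`` (HDF5 only) also returns the
    simulator ground truth when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording {path} does not exist")
    if format is None:
        format = {".h5": "hdf5", ".hdf5": "hdf5", ".csv": "csv",
                  ".fif": "fif"}.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from {path.suffix!r}")
    if format == "hdf5":
        return _read_hdf5(path, with_truth=with_truth)
    if format == "csv":
        raw = _read_csv(path)
    elif format == "fif":
        raw = _read_fif(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return (raw, None) if with_truth else raw


def write_decomposition(path, decomp: Decomposition):
    """Serialize a Decomposition to HDF5 (mixing, unmixing, sources, meta)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("mixing", data=decomp.mixing)
        f.create_dataset("unmixing", data=decomp.unmixing)
        f.create_dataset("sources", data=decomp.sources)
        meta = f.create_group("meta")
        meta.attrs["method"] = decomp.method
        if decomp.fs_hz is not None:
            meta.attrs["fs_hz"] = decomp.fs_hz
        if decomp.schedule is not None:
            meta.attrs["fp_hz"] = decomp.schedule.fp_hz
            meta.attrs["k"] = decomp.schedule.k
            meta.attrs["delays_samples"] = decomp.schedule.delays_samples
        if decomp.convergence is not None:
            meta.attrs["sweeps"] = decomp.convergence.sweeps
            meta.attrs["converged"] = decomp.convergence.converged
            meta.attrs["criterion_history"] = \
                decomp.convergence.criterion_history


def read_decomposition(path) -> Decomposition:
    with h5py.File(path, "r") as f:
        meta = f["meta"].attrs
        schedule = None
        if "delays_samples" in meta:
            schedule = DelaySchedule(
                fs_hz=float(meta["fs_hz"]), fp_hz=float(meta["fp_hz"]),
                k=int(meta["k"]),
                delays_samples=tuple(int(d) for d
                                     in meta["delays_samples"]))
        convergence = None
        if "sweeps" in meta:
            convergence = ConvergenceRecord(
                sweeps=int(meta["sweeps"]),
                converged=bool(meta["converged"]),
                criterion_history=list(meta["criterion_history"]))
        return Decomposition(
            mixing=f["mixing"][()], unmixing=f["unmixing"][()],
            sources=f["sources"][()], method=str(meta["method"]),
            fs_hz=float(meta["fs_hz"]) if "fs_hz" in meta else None,
            schedule=schedule, convergence=convergence)
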