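"""Synthetic oddball MEG generator with exported ground truth.

Emulates a 2 Hz auditory oddball design: 80% standard / 20% deviant tones at
a 500 ms stimulus onset asynchrony, delivered until at least 150 deviants
have occurred. Every epoch carries bilateral-temporal M100 onset/offset
responses; a mismatch-response (MMR) source is added only in deviant epochs
and only inside a declared post-stimulus window, so the two structural
assumptions of the weighted decomposition — the MMR lives in deviant epochs
within the MMR time range, and the obligatory responses repeat identically
epoch to epoch — hold by construction and can be asserted against the
returned ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .containers import DEVIANT, STANDARD, RawRecording

__all__ = [
    "OddballDesign", "SourceModel", "GroundTruth",
    "make_event_sequence", "make_sensor_layout", "simulate_recording",
]


@dataclass(frozen=True)
class OddballDesign:
    """Timing and probability structure of the oddball sequence."""

    soa_ms: float = 500.0
    stim_duration_ms: float = 100.0
    p_deviant: float = 0.2
    min_deviants: int = 150
    fs_hz: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.p_deviant < 1.0:
            raise ValueError("p_deviant must lie strictly in (0, 1)")
        if self.stim_duration_ms >= self.soa_ms:
            raise ValueError("stimulus must be shorter than the SOA")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.min_deviants < 1:
            raise ValueError("min_deviants must be >= 1")

    @property
    def soa_samples(self) -> int:
        return int(round(self.soa_ms * self.fs_hz / 1000.0))


def make_event_sequence(design: OddballDesign, rng=None):
    """Draw a random oddball sequence.

    Labels are i.i.d. Bernoulli(p_deviant); the sequence extends until the
    deviant count reaches ``design.min_deviants``. Onsets are strictly
    periodic at the SOA, starting one SOA into the recording so a 100 ms
    pre-stimulus segment always fits.

    Returns
    -------
    onsets : ndarray of int
    labels : ndarray of str
    """
    rng = np.random.default_rng(design.seed if rng is None else rng)
    labels = []
    n_dev = 0
    while n_dev < design.min_deviants:
        # draw in blocks for speed; expected length min_deviants/p
        block = rng.random(max(64, design.min_deviants)) < design.p_deviant
        for is_dev in block:
            labels.append(DEVIANT if is_dev else STANDARD)
            n_dev += int(is_dev)
            if n_dev >= design.min_deviants:
                break
    labels = np.array(labels, dtype=object)
    onsets = design.soa_samples * (1 + np.arange(len(labels)))
    return onsets, labels


def make_sensor_layout(n_channels: int, spacing: float = 1.0,
                       threshold: float | None = None):
    """Place channels on a near-square planar grid and build adjacency.

    Parameters
    ----------
    n_channels : int
        Number of sensors (>= 4).
    spacing : float
        Grid spacing.
    threshold : float, optional
        Neighbour distance cut-off. Defaults to ``1.1 * spacing``
        (4-connectivity on the grid).

    Returns
    -------
    positions : ndarray (n_channels, 2)
    adjacency : scipy.sparse.csr_matrix of bool, symmetric, zero diagonal
    """
    if n_channels < 4:
        raise ValueError("need at least 4 channels for a layout")
    if threshold is None:
        threshold = 1.1 * spacing
    if threshold <= 0:
        raise ValueError("adjacency threshold must be positive")
    ncols = int(np.ceil(np.sqrt(n_channels)))
    idx = np.arange(n_channels)
    positions = np.column_stack([(idx % ncols) * spacing,
                                 (idx // ncols) * spacing]).astype(float)
    d2 = ((positions[:, None, :] - positions[None, :, :]) ** 2).sum(-1)
    adj = (d2 <= threshold ** 2) & (d2 > 0)
    if not adj.any():
        raise ValueError("threshold produced an empty adjacency graph")
    adjacency = csr_matrix(adj)
    n_comp, _ = connected_components(adjacency, directed=False)
    if n_comp != 1:
        raise ValueError("adjacency graph is not connected; "
                         "increase the threshold")
    return positions, adjacency


def _gauss(t: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sd) ** 2)


def _blob(positions: np.ndarray, center, width: float) -> np.ndarray:
    """Unit-norm Gaussian spatial pattern on normalized layout coords."""
    pos = positions - positions.min(0)
    span = np.where(pos.max(0) > 0, pos.max(0), 1.0)
    pos = pos / span
    g = np.exp(-((pos - np.asarray(center)) ** 2).sum(1) / (2 * width ** 2))
    return g / np.linalg.norm(g)


@dataclass
class SourceModel:
    """Ground-truth sources mixed into the sensors.

    ``topographies`` are unit-norm spatial patterns (source x channel).
    Time courses are defined per stimulus over one SOA from onset;
    ``std_time_courses`` is used for standard events, ``dev_time_courses``
    for deviant events. Sources gated ``deviant_only`` must have an all-zero
    standard course and a deviant course confined to
    ``[mmr_start_ms, mmr_end_ms]``.
    """

    topographies: np.ndarray            # (n_sources, n_channels)
    std_time_courses: np.ndarray        # (n_sources, soa_samples), fT/cm
    dev_time_courses: np.ndarray
    gating: tuple                       # per source: "both" | "deviant_only"
    positions: np.ndarray = None        # (n_channels, 2) layout
    adaptation_factor: float = 0.7
    mmr_start_ms: float = 96.0
    mmr_end_ms: float = 276.0
    sensor_noise_sd: float = 10.0       # white noise, fT/cm
    pink_amplitude: float = 15.0        # 1/f background RMS, fT/cm
    alpha_amplitude: float = 0.0        # handled as a gated="both" source
    alpha_freq_hz: float = 10.0

    def __post_init__(self):
        self.topographies = np.atleast_2d(np.asarray(self.topographies,
                                                     dtype=float))
        self.std_time_courses = np.atleast_2d(
            np.asarray(self.std_time_courses, dtype=float))
        self.dev_time_courses = np.atleast_2d(
            np.asarray(self.dev_time_courses, dtype=float))
        n_src = self.topographies.shape[0]
        if (self.std_time_courses.shape[0] != n_src
                or self.dev_time_courses.shape[0] != n_src
                or len(self.gating) != n_src):
            raise ValueError("inconsistent source dimensions")
        if self.std_time_courses.shape != self.dev_time_courses.shape:
            raise ValueError("standard/deviant time-course shape mismatch")
        norms = np.linalg.norm(self.topographies, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("topographies must have unit Euclidean norm")
        if not 0.0 < self.adaptation_factor <= 1.0:
            raise ValueError("adaptation_factor must lie in (0, 1]")
        for j, gate in enumerate(self.gating):
            if gate not in ("both", "deviant_only"):
                raise ValueError(f"unknown gating {gate!r}")
            if gate == "deviant_only" and np.any(self.std_time_courses[j]):
                raise ValueError("deviant_only source has a non-zero "
                                 "standard time course")

    @property
    def n_sources(self) -> int:
        return self.topographies.shape[0]

    @property
    def n_channels(self) -> int:
        return self.topographies.shape[1]

    @property
    def mmr_source_index(self) -> int:
        """Index of the (first) deviant-only source, or -1 if none."""
        for j, g in enumerate(self.gating):
            if g == "deviant_only":
                return j
        return -1

    @classmethod
    def default(cls, n_channels: int = 204, design: OddballDesign = None,
                snr: float = 5.0, m100_amplitude: float = 80.0,
                adaptation_factor: float = 0.7,
                sensor_noise_sd: float = 10.0,
                pink_amplitude: float = 15.0,
                alpha_amplitude: float = 12.0) -> "SourceModel":
        """Bilateral M100 + deviant-only MMR + alpha background.

        ``snr`` sets the planted MMR peak amplitude as a multiple of the
        white sensor-noise SD. The M100 is modelled as Gaussian-windowed
        onset (peak ~100 ms post-onset) and offset (peak ~100 ms
        post-offset, i.e. ~200 ms post-onset) deflections, so the offset
        response intrudes into the MMR window just as in real auditory
        recordings; standard-epoch M100 amplitude is attenuated by
        ``adaptation_factor`` (repetition suppression).
        """
        design = design or OddballDesign()
        positions, _ = make_sensor_layout(n_channels)
        n_t = design.soa_samples
        t = np.arange(n_t) * 1000.0 / design.fs_hz  # ms from onset
        off_ms = design.stim_duration_ms + 100.0

        m100 = (m100_amplitude * _gauss(t, 100.0, 18.0)
                + 0.6 * m100_amplitude * _gauss(t, off_ms, 20.0))
        mmr_peak = snr * sensor_noise_sd
        mmr = mmr_peak * _gauss(t, 150.0, 25.0)
        mmr[(t < 96.0) | (t > 276.0)] = 0.0

        topos = np.stack([
            _blob(positions, (0.15, 0.50), 0.12),   # left temporal M100
            _blob(positions, (0.85, 0.50), 0.12),   # right temporal M100
            0.6 * _blob(positions, (0.22, 0.55), 0.14)
            + 0.4 * _blob(positions, (0.80, 0.50), 0.14),  # MMR, overlapping
            _blob(positions, (0.50, 0.85), 0.20),   # alpha background
        ])
        topos /= np.linalg.norm(topos, axis=1, keepdims=True)

        zeros = np.zeros(n_t)
        std_courses = np.stack([adaptation_factor * m100,
                                adaptation_factor * m100, zeros, zeros])
        dev_courses = np.stack([m100, m100, mmr, zeros])
        return cls(topographies=topos, std_time_courses=std_courses,
                   dev_time_courses=dev_courses,
                   gating=("both", "both", "deviant_only", "both"),
                   positions=positions,
                   adaptation_factor=adaptation_factor,
                   sensor_noise_sd=sensor_noise_sd,
                   pink_amplitude=pink_amplitude,
                   alpha_amplitude=alpha_amplitude)


@dataclass
class GroundTruth:
    """Everything the simulator knows, exported for downstream checks."""

    onsets: np.ndarray
    labels: np.ndarray
    true_mixing: np.ndarray       # (n_channels, n_sources)
    true_sources: np.ndarray      # (n_sources, n_samples)
    mmr_source_index: int
    mmr_window_ms: tuple = (96.0, 276.0)

    @property
    def mmr_topography(self) -> np.ndarray:
        return self.true_mixing[:, self.mmr_source_index]


def _pink_noise(rng, shape, fs_hz):
    """Approximate 1/f noise: white noise through a one-pole lowpass,
    rescaled to unit RMS per channel."""
    white = rng.standard_normal(shape)
    b, a = _sig.butter(1, 2.0 / (fs_hz / 2.0), btype="low")
    pink = _sig.lfilter(b, a, white, axis=-1) + 0.05 * white
    rms = np.sqrt(np.mean(pink ** 2, axis=-1, keepdims=True))
    return pink / np.where(rms > 0, rms, 1.0)


def simulate_recording(design: OddballDesign, model: SourceModel,
                       rng=None):
    """Mix the model's sources into a continuous sensor recording.

    Returns ``(RawRecording, GroundTruth)``. Sensor data are
    ``true_mixing @ true_sources`` plus 1/f background and white sensor
    noise; with all noise amplitudes zero the mixing identity is exact.
    """
    rng = np.random.default_rng(design.seed if rng is None else rng)
    onsets, labels = make_event_sequence(design, rng)
    n_t = design.soa_samples
    if model.std_time_courses.shape[1] != n_t:
        raise ValueError("time courses must span one SOA "
                         f"({n_t} samples at fs={design.fs_hz})")
    n_samples = int(onsets[-1] + 2 * n_t)
    n_src = model.n_sources

    sources = np.zeros((n_src, n_samples))
    for onset, label in zip(onsets, labels):
        courses = (model.dev_time_courses if label == DEVIANT
                   else model.std_time_courses)
        sources[:, onset:onset + n_t] += courses

    if model.alpha_amplitude > 0:
        # 10 Hz background with a fresh random phase every trial
        alpha_row = np.zeros(n_samples)
        t_rel = np.arange(n_t) / design.fs_hz
        starts = np.concatenate([[0], onsets,
                                 [onsets[-1] + n_t]]).astype(int)
        for s0 in starts:
            seg = slice(s0, min(s0 + n_t, n_samples))
            phase = rng.uniform(0, 2 * np.pi)
            alpha_row[seg] = model.alpha_amplitude * np.sin(
                2 * np.pi * model.alpha_freq_hz * t_rel[:seg.stop - s0]
                + phase)
        # attach to the last "both"-gated zero-course source if present
        alpha_idx = None
        for j in range(n_src - 1, -1, -1):
            if (model.gating[j] == "both"
                    and not model.dev_time_courses[j].any()):
                alpha_idx = j
                break
        if alpha_idx is None:
            raise ValueError("alpha_amplitude > 0 requires a spare "
                             "'both'-gated source with zero time courses")
        sources[alpha_idx] += alpha_row

    mixing = model.topographies.T  # (n_channels, n_sources)
    data = mixing @ sources
    if model.pink_amplitude > 0:
        data += model.pink_amplitude * _pink_noise(
            rng, data.shape, design.fs_hz)
    if model.sensor_noise_sd > 0:
        data += model.sensor_noise_sd * rng.standard_normal(data.shape)

    raw = RawRecording(data=data, fs_hz=design.fs_hz, onsets=onsets,
                       labels=labels, positions=model.positions)
    truth = GroundTruth(onsets=onsets, labels=labels, true_mixing=mixing,
                        true_sources=sources,
                        mmr_source_index=model.mmr_source_index,
                        mmr_window_ms=(model.mmr_start_ms,
                                       model.mmr_end_ms))
    return raw, truth
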