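"""Time-delayed second-order blind source separation (BSS_T/k).

The method assumes the target response repeats periodically at the stimulus
presentation rate f_p. It sphers the sensor data, forms symmetrized
time-lagged correlation matrices at delays tau_m = T/m (T = fs/f_p,
m = 1..k), and finds one orthogonal rotation that approximately
diagonalizes all of them simultaneously, using the Jacobi-like sweep of
closed-form Givens rotations of Cardoso & Souloumiac. Components are then
sources = V^T z with mixing columns mapped back through the desphering
transform.

An adapter around an external infomax ICA implementation exposes the
comparison method in the same Model/Results shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import RawRecording

logger = logging.getLogger(__name__)

__all__ = [
    "DelaySchedule", "compute_delays", "sphere", "lagged_correlation",
    "joint_diagonalize", "ConvergenceRecord", "Decomposition",
    "BSSTk", "InfomaxICA", "decompose_bsstk", "run_external_ica",
    "back_project",
]


@dataclass(frozen=True)
class DelaySchedule:
    """Delay set tau_m = T/m in samples, T = trunc(fs/fp)."""

    fs_hz: float
    fp_hz: float
    k: int
    delays_samples: tuple

    @property
    def delays_ms(self) -> tuple:
        return tuple(d * 1000.0 / self.fs_hz for d in self.delays_samples)


def compute_delays(fs_hz: float, fp_hz: float, k: int,
                   rounding: str = "trunc",
                   dedupe: bool = False) -> DelaySchedule:
    """Build the T/k delay schedule.

    The default integer convention is truncation, tau_m = trunc(trunc(
    fs/fp)/m), which at fs=1000 Hz, fp=2 Hz, k=8 yields the delays
    500, 250, 166, 125, 100, 83, 71, 62 samples (the nearest-integer
    alternative, which would give 167 and 63 at m=3 and m=8, is available
    via ``rounding="nearest"``).
    """
    if fs_hz <= 0 or fp_hz <= 0:
        raise ValueError("fs_hz and fp_hz must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    period = int(fs_hz / fp_hz)
    if k > period:
        raise ValueError(f"k={k} exceeds the stimulus period "
                         f"({period} samples)")
    if rounding == "trunc":
        delays = [period // m for m in range(1, k + 1)]
    elif rounding == "nearest":
        delays = [int(round(period / m)) for m in range(1, k + 1)]
    else:
        raise ValueError(f"unknown rounding {rounding!r}")
    if dedupe:
        seen, uniq = set(), []
        for d in delays:
            if d not in seen:
                uniq.append(d)
                seen.add(d)
        delays = uniq
    return DelaySchedule(fs_hz=fs_hz, fp_hz=fp_hz, k=k,
                         delays_samples=tuple(delays))


def sphere(data: np.ndarray, rank_tol: float = 1e-10, center: bool = False):
    """Whiten the data by eigendecomposition of the sample covariance.

    Eigenvalues below ``rank_tol`` times the largest are dropped, so
    rank-deficient inputs (e.g. after spatial filtering) are projected onto
    their signal subspace.

    Returns
    -------
    whitened : ndarray (rank, n_samples) — identity covariance
    sphering : ndarray (rank, n_channels)
    desphering : ndarray (n_channels, rank) — right-inverse of sphering
    rank : int
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D array with at least 2 channels")
    n_ch, n_samp = X.shape
    if n_samp <= n_ch:
        raise ValueError("need more samples than channels")
    if center:
        X = X - X.mean(axis=1, keepdims=True)
    cov = X @ X.T / n_samp
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 0:
        raise ValueError("data have zero variance")
    keep = evals > rank_tol * evals[0]
    rank = int(keep.sum())
    evals, evecs = evals[:rank], evecs[:, :rank]
    sph = evecs.T / np.sqrt(evals)[:, None]
    desph = evecs * np.sqrt(evals)[None, :]
    return sph @ X, sph, desph, rank


def lagged_correlation(whitened: np.ndarray, delay: int,
                       normalize: bool = True) -> np.ndarray:
    """Symmetrized time-lagged correlation matrix R(tau).

    Uses the overlapping-segment estimator with denominator equal to the
    number of overlapping samples, symmetrizes as (R + R^T)/2, and (by
    default) scales to unit Frobenius norm so every lag carries equal
    weight in the joint-diagonalization criterion.
    """
    Z = np.asarray(whitened, dtype=float)
    n = Z.shape[1]
    if delay < 0:
        raise ValueError("delay must be non-negative")
    if delay >= n:
        raise ValueError(f"delay {delay} >= sample count {n}")
    if delay == 0:
        R = Z @ Z.T / n
    else:
        R = Z[:, :-delay] @ Z[:, delay:].T / (n - delay)
    R = 0.5 * (R + R.T)
    if normalize:
        nrm = np.linalg.norm(R)
        if nrm > 0:
            R = R / nrm
    return R


@dataclass
class ConvergenceRecord:
    """Diagnostics of the Jacobi sweeps."""

    sweeps: int = 0
    converged: bool = False
    tol: float = 1e-8
    criterion_history: list = field(default_factory=list)

    @property
    def final_criterion(self) -> float:
        return self.criterion_history[-1] if self.criterion_history else np.nan


def _offdiag_criterion(M: np.ndarray) -> float:
    """Summed squared off-diagonal entries over a matrix stack."""
    d = np.einsum("kii->ki", M)
    return float((M ** 2).sum() - (d ** 2).sum())


def joint_diagonalize(matrices, tol: float = 1e-8, max_sweeps: int = 100):
    """Jointly diagonalize symmetric matrices by Givens-rotation sweeps.

    Finds the orthogonal V minimizing the summed squared off-diagonal
    entries of {V^T M_i V}. Each index pair (p, q) is rotated by the
    closed-form angle of Cardoso & Souloumiac; sweeps stop when every
    rotation angle in a full sweep falls below ``tol`` radians.
    Non-convergence within ``max_sweeps`` is a logged warning.

    Returns ``(V, ConvergenceRecord)``. The record's criterion history is
    non-increasing across sweeps.
    """
    M = np.stack([np.asarray(m, dtype=float) for m in matrices])
    if M.ndim != 3 or M.shape[1] != M.shape[2]:
        raise ValueError("matrices must be square and equally sized")
    if not np.allclose(M, np.swapaxes(M, 1, 2), atol=1e-8 * max(
            1.0, float(np.abs(M).max()))):
        raise ValueError("matrices must be symmetric")
    n = M.shape[1]
    V = np.eye(n)
    record = ConvergenceRecord(tol=tol)
    record.criterion_history.append(_offdiag_criterion(M))
    for sweep in range(max_sweeps):
        max_theta = 0.0
        for p in range(n - 1):
            for q in range(p + 1, n):
                ton = M[:, p, p] - M[:, q, q]
                toff = M[:, p, q] + M[:, q, p]
                g11 = ton @ ton
                g12 = ton @ toff
                g22 = toff @ toff
                x = g11 - g22
                y = 2.0 * g12
                r = np.hypot(x, y)
                if r <= 0:
                    continue
                theta = 0.5 * np.arctan2(y, x + r)
                if abs(theta) > max_theta:
                    max_theta = abs(theta)
                if abs(theta) < tol:
                    continue
                c, s = np.cos(theta), np.sin(theta)
                # congruence update M <- G^T M G in the (p, q) plane
                Mp = M[:, :, p].copy()
                Mq = M[:, :, q]
                M[:, :, p] = c * Mp + s * Mq
                M[:, :, q] = -s * Mp + c * Mq
                Mp = M[:, p, :].copy()
                Mq = M[:, q, :]
                M[:, p, :] = c * Mp + s * Mq
                M[:, q, :] = -s * Mp + c * Mq
                Vp = V[:, p].copy()
                V[:, p] = c * Vp + s * V[:, q]
                V[:, q] = -s * Vp + c * V[:, q]
        record.sweeps = sweep + 1
        record.criterion_history.append(_offdiag_criterion(M))
        if max_theta < tol:
            record.converged = True
            break
    if not record.converged:
        logger.warning("joint_diagonalize: no convergence within %d sweeps "
                       "(last max angle still >= %g rad)", max_sweeps, tol)
    return V, record


def _fix_signs(mixing, unmixing, sources):
    """Resolve the per-component sign indeterminacy deterministically:
    the largest-|entry| element of each mixing column is made positive."""
    idx = np.argmax(np.abs(mixing), axis=0)
    flip = np.sign(mixing[idx, np.arange(mixing.shape[1])])
    flip[flip == 0] = 1.0
    return mixing * flip, unmixing * flip[:, None], sources * flip[:, None]


@dataclass
class Decomposition:
    """Results of a linear decomposition x(n) = A s(n).

    ``mixing`` is the channel x component matrix A, ``unmixing`` its
    component x channel left-inverse W on the retained subspace, and
    ``sources`` the component x sample signals s. The retained rank equals
    the component count (204 for full-rank 204-channel input).
    """

    mixing: np.ndarray
    unmixing: np.ndarray
    sources: np.ndarray
    method: str                      # "bsstk" | "ica"
    fs_hz: float = None
    schedule: DelaySchedule = None
    convergence: ConvergenceRecord = None

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    @property
    def n_channels(self) -> int:
        return self.mixing.shape[0]

    def reconstruct(self) -> np.ndarray:
        """Full back-projection A s(n) of every component."""
        return self.mixing @ self.sources

    def back_project(self, components) -> np.ndarray:
        """Sensor-space contribution of a component subset (A_Q s_Q)."""
        return back_project(self, components)

    def source_variance(self) -> np.ndarray:
        """Sensor-space variance carried by each component."""
        col_power = (self.mixing ** 2).sum(axis=0)
        src_power = (self.sources ** 2).mean(axis=1)
        return col_power * src_power

    def summary(self) -> str:
        lines = [
            "Decomposition Results",
            "=" * 54,
            f"method:            {self.method}",
            f"channels:          {self.n_channels}",
            f"components:        {self.n_components}",
            f"samples:           {self.sources.shape[1]}",
        ]
        if self.schedule is not None:
            ms = ", ".join(f"{d:.0f}" for d in self.schedule.delays_ms)
            lines.append(f"delays (ms):       {ms}")
        if self.convergence is not None:
            lines.append(f"sweeps:            {self.convergence.sweeps} "
                         f"(converged={self.convergence.converged})")
            lines.append("off-diag criterion: "
                         f"{self.convergence.final_criterion:.3e}")
        var = self.source_variance()
        order = np.argsort(var)[::-1][:5]
        frac = var / var.sum() if var.sum() > 0 else var
        lines.append("top components by sensor variance:")
        for q in order:
            lines.append(f"  #{q:<4d} {100 * frac[q]:6.2f} %")
        return "\n".join(lines)


def back_project(decomp: Decomposition, components) -> np.ndarray:
    """Back-project a subset Q of components into sensor space."""
    Q = np.atleast_1d(np.asarray(components, dtype=int))
    if Q.size == 0:
        raise ValueError("component subset must be non-empty")
    if Q.min() < 0 or Q.max() >= decomp.n_components:
        raise ValueError("component index out of range")
    return decomp.mixing[:, Q] @ decomp.sources[Q]


def _as_array(data):
    if isinstance(data, RawRecording):
        return data.data, data.fs_hz
    return np.asarray(data, dtype=float), None


class BSSTk:
    """BSS_T/k model: joint diagonalization of T/m lagged correlations.

    Parameters
    ----------
    data : RawRecording or ndarray (n_channels, n_samples)
        Sensor data (for the weighted approach: the window-weighted
        concatenated deviant epochs).
    fs_hz : float
        Sampling rate (taken from the recording when one is given).
    fp_hz : float
        Stimulus presentation rate; the fundamental delay is T = fs/fp.
    k : int
        Number of fractional delays T/1 .. T/k.
    schedule : DelaySchedule, optional
        Overrides (fp_hz, k).
    normalize_lags : bool
        Scale each symmetrized lag matrix to unit Frobenius norm.
    center : bool
        Remove channel means before sphering.

    Examples
    --------
    >>> model = BSSTk(weighted_raw, fp_hz=2.0, k=8)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, data, fs_hz: float = None, fp_hz: float = 2.0,
                 k: int = 8, schedule: DelaySchedule = None,
                 normalize_lags: bool = True, center: bool = False,
                 rank_tol: float = 1e-10):
        self.data, rec_fs = _as_array(data)
        self.fs_hz = fs_hz if fs_hz is not None else rec_fs
        if self.fs_hz is None:
            raise ValueError("fs_hz required when data is a bare array")
        self.schedule = schedule or compute_delays(self.fs_hz, fp_hz, k)
        self.normalize_lags = normalize_lags
        self.center = center
        self.rank_tol = rank_tol

    def fit(self, tol: float = 1e-8, max_sweeps: int = 100) -> Decomposition:
        Z, sph, desph, rank = sphere(self.data, rank_tol=self.rank_tol,
                                     center=self.center)
        mats = [lagged_correlation(Z, d, normalize=self.normalize_lags)
                for d in self.schedule.delays_samples]
        V, record = joint_diagonalize(mats, tol=tol, max_sweeps=max_sweeps)
        sources = V.T @ Z
        mixing = desph @ V
        unmixing = V.T @ sph
        mixing, unmixing, sources = _fix_signs(mixing, unmixing, sources)
        logger.info("BSSTk: %d components, %d sweeps (converged=%s)",
                    rank, record.sweeps, record.converged)
        return Decomposition(mixing=mixing, unmixing=unmixing,
                             sources=sources, method="bsstk",
                             fs_hz=self.fs_hz, schedule=self.schedule,
                             convergence=record)


class InfomaxICA:
    """Thin adapter around an external (extended) infomax implementation.

    Sphering and rank handling mirror :class:`BSSTk`; the rotation comes
    from ``mne.preprocessing.infomax`` (an optional dependency), and the
    returned object uses the same sign and ordering conventions.
    """

    def __init__(self, data, fs_hz: float = None, seed: int = 0,
                 extended: bool = True, max_iter: int = 200,
                 center: bool = True, rank_tol: float = 1e-10):
        self.data, rec_fs = _as_array(data)
        self.fs_hz = fs_hz if fs_hz is not None else rec_fs
        self.seed = seed
        self.extended = extended
        self.max_iter = max_iter
        self.center = center
        self.rank_tol = rank_tol

    def fit(self) -> Decomposition:
        try:
            from mne.preprocessing import infomax as _infomax
        except ImportError as err:  # pragma: no cover - env dependent
            raise ImportError(
                "the ICA adapter requires the optional dependency 'mne' "
                "(pip install mne)") from err
        Z, sph, desph, rank = sphere(self.data, rank_tol=self.rank_tol,
                                     center=self.center)
        U = _infomax(Z.T, extended=self.extended, max_iter=self.max_iter,
                     random_state=self.seed)
        sources = U @ Z
        mixing = desph @ np.linalg.inv(U)
        unmixing = U @ sph
        mixing, unmixing, sources = _fix_signs(mixing, unmixing, sources)
        logger.info("InfomaxICA: %d components (seed=%s)", rank, self.seed)
        return Decomposition(mixing=mixing, unmixing=unmixing,
                             sources=sources, method="ica",
                             fs_hz=self.fs_hz)


def decompose_bsstk(data, schedule: DelaySchedule = None,
                    fs_hz: float = None, fp_hz: float = 2.0, k: int = 8,
                    tol: float = 1e-8, max_sweeps: int = 100,
                    **kwargs) -> Decomposition:
    """Functional one-shot interface to :class:`BSSTk`."""
    model = BSSTk(data, fs_hz=fs_hz, fp_hz=fp_hz, k=k, schedule=schedule,
                  **kwargs)
    return model.fit(tol=tol, max_sweeps=max_sweeps)


def run_external_ica(data, seed: int = 0, fs_hz: float = None,
                     **kwargs) -> Decomposition:
    """Functional one-shot interface to :class:`InfomaxICA`."""
    return InfomaxICA(data, fs_hz=fs_hz, seed=seed, **kwargs).fit()
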