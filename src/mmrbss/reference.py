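"""Reference standard for the mismatch response.

The only accepted way to localize the MMR is sensor-space subtraction, so
the reference against which decomposition components are scored is the
subtraction difference waveform restricted to MMR sensors and the MMR time
window. Sensors and window are found data-driven by a spatio-temporal
cluster permutation test on per-subject difference ERFs: one-sample t maps
are thresholded, supra-threshold samples are clustered over the combined
spatial x temporal adjacency, and cluster masses are referred to a
max-statistic null built from random sign flips of subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import t as _tdist

from .containers import Erf

logger = logging.getLogger(__name__)

__all__ = ["ClusterResult", "ReferenceStandard",
           "spatiotemporal_cluster_test", "build_reference",
           "reference_from_clusters"]


@dataclass
class ClusterResult:
    """Outcome of the spatio-temporal cluster permutation test."""

    t_map: np.ndarray                 # (n_channels, n_times)
    clusters: list                    # list of (ch_idx, t_idx) index arrays
    masses: np.ndarray                # signed sum of member t-values
    p_values: np.ndarray
    n_permutations: int
    seed: int = None

    def significant(self, alpha: float = 0.05) -> list:
        """Indices of clusters with p <= alpha, ordered by p."""
        sig = [i for i in range(len(self.clusters))
               if self.p_values[i] <= alpha]
        return sorted(sig, key=lambda i: self.p_values[i])


@dataclass
class ReferenceStandard:
    """MMR sensor subset, time window, and the reference matrix.

    ``matrix`` holds the difference ERF restricted to the L selected
    channels and the [n1, n2] window (L x window-samples, fT/cm).
    """

    channels: np.ndarray              # L channel indices into the full set
    window_ms: tuple                  # (n1_ms, n2_ms)
    matrix: np.ndarray
    times_ms: np.ndarray = None       # window time axis
    provenance: str = "manual"

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=int)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != len(self.channels):
            raise ValueError("matrix rows must match selected channels")
        if not np.isfinite(self.matrix).all():
            raise ValueError("reference matrix contains non-finite values")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def restrict(self, sensor_erf: np.ndarray,
                 times_ms: np.ndarray) -> np.ndarray:
        """Apply the channel selection and window to a channel x time
        array defined on ``times_ms``."""
        n1, n2 = self.window_ms
        cols = (times_ms >= n1) & (times_ms <= n2)
        out = np.asarray(sensor_erf)[self.channels][:, cols]
        if out.shape != self.matrix.shape:
            raise ValueError("restricted array does not match the "
                             "reference shape")
        return out


def _st_adjacency(spatial_adj, n_times: int) -> sparse.csr_matrix:
    """Combined spatio-temporal adjacency on (channel, time) nodes,
    flattened channel-major."""
    n_ch = spatial_adj.shape[0]
    eye_t = sparse.identity(n_times, format="csr", dtype=bool)
    eye_c = sparse.identity(n_ch, format="csr", dtype=bool)
    t_adj = sparse.diags([np.ones(n_times - 1)] * 2, [1, -1],
                         format="csr").astype(bool)
    spatial_adj = sparse.csr_matrix(spatial_adj).astype(bool)
    return (sparse.kron(spatial_adj, eye_t)
            + sparse.kron(eye_c, t_adj)).tocsr()


def _clusters_from_tmap(t_flat: np.ndarray, thresh: float,
                        st_adj: sparse.csr_matrix):
    """Cluster supra-threshold samples; positive and negative separately.

    Returns (list of member-index arrays, array of signed masses)."""
    members, masses = [], []
    for sign in (1.0, -1.0):
        mask = sign * t_flat > thresh
        k = int(mask.sum())
        if k == 0:
            continue
        idx = np.flatnonzero(mask)
        sub = st_adj[idx][:, idx]
        n_comp, labels = connected_components(sub, directed=False)
        for c in range(n_comp):
            nodes = idx[labels == c]
            members.append(nodes)
            masses.append(float(t_flat[nodes].sum()))
    return members, np.array(masses)


def spatiotemporal_cluster_test(difference_erfs, adjacency,
                                n_permutations: int = 1024,
                                cluster_p: float = 0.01,
                                seed: int = None) -> ClusterResult:
    """Cluster-level permutation test of difference ERFs against zero.

    Parameters
    ----------
    difference_erfs : ndarray (n_subjects, n_channels, n_times) or list of Erf
        One difference waveform per subject on shared axes.
    adjacency : sparse or dense (n_channels, n_channels) boolean
        Spatial sensor adjacency; must be connected.
    n_permutations : int
        Number of random subject sign-flips forming the null.
    cluster_p : float
        Two-sided cluster-defining threshold on the one-sample t map.
    seed : int
        Seed for the sign-flip draw.

    Notes
    -----
    Cluster mass is the signed sum of member t-values; positive and
    negative clusters are formed separately and referred two-sidedly to
    the null distribution of the maximum absolute mass, with the +1
    small-sample correction p = (1 + #{null >= |mass|}) / (1 + n_perm).
    """
    if isinstance(difference_erfs, (list, tuple)) and isinstance(
            difference_erfs[0], Erf):
        X = np.stack([e.data for e in difference_erfs])
    else:
        X = np.asarray(difference_erfs, dtype=float)
    if X.ndim != 3:
        raise ValueError("expected (n_subjects, n_channels, n_times)")
    n_subj, n_ch, n_t = X.shape
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    adj = sparse.csr_matrix(adjacency).astype(bool)
    if adj.shape != (n_ch, n_ch):
        raise ValueError("adjacency shape does not match channel count")
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp != 1:
        raise ValueError("spatial adjacency must be connected")

    df = n_subj - 1
    thresh = _tdist.ppf(1 - cluster_p / 2.0, df)
    st_adj = _st_adjacency(adj, n_t)

    Xf = X.reshape(n_subj, -1)
    sumsq = (Xf ** 2).sum(axis=0)

    def t_stat(signs):
        mean = signs @ Xf / n_subj
        var = (sumsq - n_subj * mean ** 2) / df
        var = np.maximum(var, 1e-300)
        return mean / np.sqrt(var / n_subj)

    t_obs = t_stat(np.ones(n_subj))
    members, masses = _clusters_from_tmap(t_obs, thresh, st_adj)

    rng = np.random.default_rng(seed)
    null = np.zeros(n_permutations)
    flips = rng.choice([-1.0, 1.0], size=(n_permutations, n_subj))
    for i in range(n_permutations):
        t_perm = t_stat(flips[i])
        _, m = _clusters_from_tmap(t_perm, thresh, st_adj)
        null[i] = np.abs(m).max() if m.size else 0.0

    if masses.size:
        p_values = np.array([(1 + (null >= abs(m)).sum())
                             / (1 + n_permutations) for m in masses])
    else:
        p_values = np.array([])
    clusters = [(np.asarray(nodes) // n_t, np.asarray(nodes) % n_t)
                for nodes in members]
    logger.info("cluster test: %d cluster(s), min p = %s", len(clusters),
                p_values.min() if p_values.size else "n/a")
    return ClusterResult(t_map=t_obs.reshape(n_ch, n_t), clusters=clusters,
                         masses=masses, p_values=p_values,
                         n_permutations=n_permutations, seed=seed)


def build_reference(difference_erf: Erf, channels, window_ms,
                    provenance: str = "manual") -> ReferenceStandard:
    """Restrict a difference ERF to MMR channels and the MMR window.

    Selects the stated rows and the window's time columns with no
    rescaling.
    """
    channels = np.atleast_1d(np.asarray(channels, dtype=int))
    if channels.size == 0:
        raise ValueError("channel selection must be non-empty")
    n1, n2 = float(window_ms[0]), float(window_ms[1])
    if not n1 < n2:
        raise ValueError("window requires n1 < n2")
    cols = (difference_erf.times_ms >= n1) & (difference_erf.times_ms <= n2)
    if not cols.any():
        raise ValueError("window selects no samples of the ERF time axis")
    matrix = difference_erf.data[channels][:, cols]
    return ReferenceStandard(channels=channels, window_ms=(n1, n2),
                             matrix=matrix,
                             times_ms=difference_erf.times_ms[cols],
                             provenance=provenance)


def reference_from_clusters(difference_erf: Erf, result: ClusterResult,
                            cluster_ids) -> ReferenceStandard:
    """Build the reference from an explicit selection of clusters.

    Channels are the union of the selected clusters' channels; the window
    spans the earliest to latest time sample across them. Cluster choice
    is deliberately an argument (mirroring manual selection of the
    physiologically plausible clusters), never automatic.
    """
    cluster_ids = list(np.atleast_1d(cluster_ids))
    if not cluster_ids:
        raise ValueError("select at least one cluster")
    chans, t_idx = set(), []
    for cid in cluster_ids:
        ch, tt = result.clusters[cid]
        chans.update(ch.tolist())
        t_idx.extend(tt.tolist())
    times = difference_erf.times_ms
    window = (float(times[min(t_idx)]), float(times[max(t_idx)]))
    return build_reference(difference_erf, sorted(chans), window,
                           provenance=f"clusters {sorted(cluster_ids)}")
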