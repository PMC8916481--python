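"""Scoring decomposition components against the MMR reference standard.

Spatial resemblance is the (absolute) cosine between a component's mixing
column and the reference pattern at each window time, maximized over the
window (C_max, unitless in [0, 1]). Temporal resemblance is the
amplitude-carrying scalar projection of the back-projected, reference-
restricted waveform onto each reference row, maximized over sensors
(M_max, fT/cm-scaled; may be negative for anti-correlated components).
Components are classified in the z-scored (M_max, C_max) plane, salient
ones are summarized by 2-D PCA, and their contribution is quantified by
cumulative back-projection: the increment of the mean projection M_ave per
added component (relative contribution), fitted by a decaying exponential
whose crossing of the 5% threshold counts the dominant components.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .decompose import Decomposition, back_project
from .reference import ReferenceStandard

logger = logging.getLogger(__name__)

__all__ = [
    "cosine_similarity_max", "morphology_similarity_max", "zscore_pool",
    "classify_quadrants", "pca_salient", "SalientSummary",
    "score_components", "cumulative_mave", "full_reconstruction_mave",
    "relative_contribution", "fit_exponential", "ExponentialFit",
    "count_dominant", "ContributionProfile", "QUADRANT_ROLES",
]

QUADRANT_ROLES = {"RU": "major", "LU": "minor", "RL": "pseudo",
                  "LL": "inconsequential"}


def cosine_similarity_max(reference: ReferenceStandard,
                          mixing_column: np.ndarray) -> float:
    """Maximum absolute cosine between the reference's spatial pattern at
    each window time and the component's mixing column.

    A full-length (N-channel) column is restricted to the reference's L
    channels before normalization; an L-length column is used as given.
    """
    b = np.asarray(mixing_column, dtype=float).ravel()
    L = reference.n_channels
    if b.size != L:
        b = b[reference.channels]
    nb = np.linalg.norm(b)
    if nb == 0:
        raise ValueError("mixing column has zero norm on the MMR sensors")
    col_norms = np.linalg.norm(reference.matrix, axis=0)
    if np.any(col_norms == 0):
        raise ValueError("reference has a zero-norm spatial pattern")
    cos = np.abs(reference.matrix.T @ b) / (col_norms * nb)
    return float(cos.max())


def morphology_similarity_max(reference: ReferenceStandard,
                              projected: np.ndarray,
                              absolute: bool = False,
                              centered: bool = False) -> float:
    """Maximum (signed) scalar projection M_l = (X_l, Y_l)/||X_l|| over
    the reference sensors.

    X_l is a reference row, Y_l the matching row of the back-projected,
    window-restricted data. The projection carries Y's amplitude, so
    components are compared on the sensor scale regardless of their
    internal normalization. ``centered=True`` removes row means first
    (Pearson-style variant); ``absolute=True`` maximizes |M_l|.
    """
    Y = np.asarray(projected, dtype=float)
    if Y.shape != reference.matrix.shape:
        raise ValueError(f"projected shape {Y.shape} does not match the "
                         f"reference {reference.matrix.shape}")
    X = reference.matrix
    if centered:
        X = X - X.mean(axis=1, keepdims=True)
        Y = Y - Y.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValueError("reference has a zero-norm sensor waveform")
    m = (X * Y).sum(axis=1) / norms
    return float(np.abs(m).max() if absolute else m.max())


def _morphology_per_channel(reference, projected, centered=False):
    X, Y = reference.matrix, np.asarray(projected, dtype=float)
    if centered:
        X = X - X.mean(axis=1, keepdims=True)
        Y = Y - Y.mean(axis=1, keepdims=True)
    return (X * Y).sum(axis=1) / np.linalg.norm(X, axis=1)


def zscore_pool(values_by_method: dict) -> dict:
    """Standardize one metric over the pool of all methods' components.

    Uses the population standard deviation over the concatenated pool
    (e.g. 204 components x 4 methods = 816 values) and returns arrays in
    the input's keying.
    """
    keys = list(values_by_method)
    arrays = [np.asarray(values_by_method[k], dtype=float) for k in keys]
    pool = np.concatenate(arrays)
    if pool.size < 2:
        raise ValueError("pool must contain at least 2 values")
    mu, sd = pool.mean(), pool.std()
    if sd == 0:
        raise ValueError("pooled values have zero spread")
    return {k: (a - mu) / sd for k, a in zip(keys, arrays)}


def classify_quadrants(z_m: np.ndarray, z_c: np.ndarray,
                       threshold: float = 1.65):
    """Quadrant labels in the z-scored (M_max, C_max) plane.

    RU (major): both above threshold; LU (minor): only C_max; RL
    (pseudo): only M_max; LL (inconsequential): neither. Salient = not LL.

    Returns ``(labels, salient_mask)``.
    """
    z_m = np.asarray(z_m, dtype=float)
    z_c = np.asarray(z_c, dtype=float)
    if not (np.isfinite(z_m).all() and np.isfinite(z_c).all()):
        raise ValueError("z-scores must be finite")
    hi_m, hi_c = z_m > threshold, z_c > threshold
    labels = np.where(hi_m & hi_c, "RU",
                      np.where(hi_c, "LU", np.where(hi_m, "RL", "LL")))
    return labels, labels != "LL"


@dataclass
class SalientSummary:
    """2-D PCA summary of salient components in the z-score plane."""

    ids: np.ndarray
    center: tuple                  # (mean z_M, mean z_C)
    pc1_slope: float               # delta z_C / delta z_M along PC1
    pc1_variance_fraction: float
    order: np.ndarray              # ids sorted by descending PC1 projection


def pca_salient(z_m, z_c, ids=None) -> SalientSummary:
    """PCA of salient points; center, PC1 slope and variance fraction.

    PC1's sign is fixed toward positive z_M, so the slope's sign encodes
    whether spatial and temporal resemblance grow together. With fewer
    than 5 points the summary is computed but flagged unreliable.
    """
    z_m = np.atleast_1d(np.asarray(z_m, dtype=float))
    z_c = np.atleast_1d(np.asarray(z_c, dtype=float))
    n = z_m.size
    if n < 2:
        raise ValueError("PCA needs at least 2 salient components")
    if n < 5:
        logger.warning("pca_salient: only %d points; summary unreliable", n)
    ids = np.arange(n) if ids is None else np.asarray(ids)
    pts = np.column_stack([z_m, z_c])
    center = pts.mean(axis=0)
    cov = np.cov((pts - center).T, bias=False) if n > 1 else np.zeros((2, 2))
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    pc1 = evecs[:, -1]
    if pc1[0] < 0 or (pc1[0] == 0 and pc1[1] < 0):
        pc1 = -pc1
    slope = np.inf if pc1[0] == 0 else pc1[1] / pc1[0]
    total = evals.sum()
    var_frac = float(evals[-1] / total) if total > 0 else 1.0
    proj = (pts - center) @ pc1
    # descending PC1 projection; ties by descending z_M, then id
    order = np.lexsort((ids, -z_m, -proj))
    return SalientSummary(ids=ids, center=(float(center[0]),
                                           float(center[1])),
                          pc1_slope=float(slope),
                          pc1_variance_fraction=var_frac,
                          order=ids[order])


def score_components(decomp: Decomposition, reference: ReferenceStandard,
                     erf_builder) -> pd.DataFrame:
    """Per-component C_max and M_max against the reference.

    ``erf_builder`` maps back-projected sensor data (n_channels x
    n_samples) to an Erf on the approach's time axis; it encodes whether
    the ERF is the subtraction difference or the weighted deviant average.
    """
    rows = []
    for q in range(decomp.n_components):
        c_max = cosine_similarity_max(reference, decomp.mixing[:, q])
        erf = erf_builder(back_project(decomp, [q]))
        Z = reference.restrict(erf.data, erf.times_ms)
        m_max = morphology_similarity_max(reference, Z)
        rows.append((q, c_max, m_max))
    return pd.DataFrame(rows, columns=["component", "C_max", "M_max"])


def cumulative_mave(decomp: Decomposition, ordered_ids,
                    reference: ReferenceStandard, erf_builder,
                    centered: bool = False) -> np.ndarray:
    """Mean projection M_ave after cumulative back-projection.

    For c = 1..#end, the first c components of ``ordered_ids`` are
    back-projected together, the approach's ERF is rebuilt, restricted to
    the reference sensors and window, and the mean of M over the L
    channels (not the max) recorded.
    """
    ordered_ids = list(np.atleast_1d(ordered_ids))
    if not ordered_ids:
        raise ValueError("ordering must be non-empty")
    out = np.empty(len(ordered_ids))
    for i in range(len(ordered_ids)):
        erf = erf_builder(back_project(decomp, ordered_ids[:i + 1]))
        Z = reference.restrict(erf.data, erf.times_ms)
        out[i] = _morphology_per_channel(reference, Z,
                                         centered=centered).mean()
    return out


def full_reconstruction_mave(decomp: Decomposition,
                             reference: ReferenceStandard,
                             erf_builder) -> float:
    """M_ave of the all-components back-projection (the RC denominator).

    For the subtraction approach this reproduces the reference exactly,
    so it equals the reference's mean self-projection mean_l ||X_l||.
    """
    return float(cumulative_mave(decomp, list(range(decomp.n_components)),
                                 reference, erf_builder)[-1])


def relative_contribution(mave_seq: np.ndarray,
                          denominator: float) -> np.ndarray:
    """RC(c) = (M_ave(c) - M_ave(c-1)) / M_ave(q_all), with M_ave(0) = 0.

    Values may be negative (components that pull the reconstruction away
    from the reference). Over a full ordering under the subtraction
    approach the sequence telescopes to sum(RC) = 1.
    """
    if denominator == 0:
        raise ValueError("RC denominator must be non-zero")
    m = np.concatenate([[0.0], np.asarray(mave_seq, dtype=float)])
    return np.diff(m) / denominator


@dataclass
class ExponentialFit:
    """Least-squares fit of RC(c) ~ beta * exp(-alpha * c)."""

    alpha: float
    beta: float
    residual: float = np.nan
    n_points: int = 0

    def predict(self, c):
        return self.beta * np.exp(-self.alpha * np.asarray(c, dtype=float))


def fit_exponential(rc: np.ndarray, c: np.ndarray = None) -> ExponentialFit:
    """Fit the decaying exponential to the (c, RC) points.

    Initialized from a log-linear regression on the positive RC values;
    alpha is unconstrained in sign (a flat or rising sequence fits with
    alpha <= 0).
    """
    rc = np.asarray(rc, dtype=float)
    if rc.size < 2:
        raise ValueError("need at least 2 points to fit")
    c = np.arange(1, rc.size + 1, dtype=float) if c is None \
        else np.asarray(c, dtype=float)
    pos = rc > 0
    if not pos.any():
        raise ValueError("no positive RC values to initialize the fit")
    slope, inter = np.polyfit(c[pos], np.log(rc[pos]), 1) if pos.sum() > 1 \
        else (0.0, np.log(rc[pos][0]))
    p0 = (-slope, np.exp(inter))
    try:
        with warnings.catch_warnings():
            # 2-point fits are exact; their covariance is undefined
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(lambda x, a, b: b * np.exp(-a * x), c, rc,
                                p0=p0, maxfev=10000)
    except RuntimeError:
        popt = p0
    alpha, beta = float(popt[0]), float(popt[1])
    resid = float(np.sum((rc - beta * np.exp(-alpha * c)) ** 2))
    return ExponentialFit(alpha=alpha, beta=beta, residual=resid,
                          n_points=rc.size)


def count_dominant(alpha: float, beta: float, threshold: float = 0.05,
                   n_end: int = None) -> int:
    """Number of dominant components: the largest c with the fitted curve
    at or above the threshold (0, i.e. "none", if it is already below at
    c = 1). A non-decaying fit (alpha <= 0) is capped at ``n_end``."""
    if not (np.isfinite(alpha) and np.isfinite(beta)):
        raise ValueError("fit parameters must be finite")
    if beta * np.exp(-alpha) < threshold:
        return 0
    if alpha <= 0:
        if n_end is None:
            raise ValueError("alpha <= 0 requires n_end to cap the count")
        return int(n_end)
    if threshold <= 0:
        if n_end is None:
            raise ValueError("threshold <= 0 requires n_end to cap")
        return int(n_end)
    count = int(np.floor(np.log(beta / threshold) / alpha + 1e-12))
    while beta * np.exp(-alpha * (count + 1)) >= threshold:
        count += 1
    while count > 1 and beta * np.exp(-alpha * count) < threshold:
        count -= 1
    if n_end is not None:
        count = min(count, int(n_end))
    return count


@dataclass
class ContributionProfile:
    """Ordered salient components with cumulative M_ave, RC, and the
    exponential-fit dominance summary."""

    ordered_ids: np.ndarray
    mave: np.ndarray
    rc: np.ndarray
    denominator: float
    fit: ExponentialFit = None
    dominant_count: int = 0

    @classmethod
    def from_decomposition(cls, decomp, ordered_ids, reference,
                           erf_builder, threshold: float = 0.05):
        """Full contribution analysis for one method's salient ordering."""
        mave = cumulative_mave(decomp, ordered_ids, reference, erf_builder)
        denom = full_reconstruction_mave(decomp, reference, erf_builder)
        rc = relative_contribution(mave, denom)
        fit = None
        dominant = 0
        if rc.size >= 2 and (rc > 0).any():
            fit = fit_exponential(rc)
            dominant = count_dominant(fit.alpha, fit.beta, threshold,
                                      n_end=rc.size)
        elif rc.size == 1:
            dominant = int(rc[0] >= threshold)
        return cls(ordered_ids=np.asarray(ordered_ids), mave=mave, rc=rc,
                   denominator=denom, fit=fit, dominant_count=dominant)
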