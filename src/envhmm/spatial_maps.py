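"""Partial-correlation spatial maps: which voxels go with which state.

The Viterbi path is expanded into a (T, K) indicator design matrix; both
the design and the full-rank (pre-whitening) envelope data are z-scored,
and a multiple regression per voxel yields one spatial map per state.

Identifiability caveat: when the K indicator columns are mutually
exclusive and exhaustive they are exactly collinear after z-scoring
(rank K-1), and the partial correlation of one state given the others is
undefined — the residual of any column on the rest is identically zero.
In that case the GLM returns the minimum-norm standardized coefficients
on the (K-1)-dimensional effective space (computed by pseudoinverse) and
logs a note.  For full-column-rank designs the returned coefficients are
exact partial correlation coefficients, identical to residualizing both
the voxel and the column on all other columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import EnvelopeDataset, StatePath

__all__ = [
    "DesignMatrix",
    "PartialCorrelationMap",
    "build_design_matrix",
    "partial_correlation_maps",
    "threshold_map",
]

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-8


@dataclass
class DesignMatrix:
    """(T, K) 0/1 state indicators; each row sums to 1."""

    X: np.ndarray
    n_states: int

    @property
    def column_sums(self) -> np.ndarray:
        return self.X.sum(axis=0)


@dataclass
class PartialCorrelationMap:
    """(K, V) coefficients between state indicators and voxel envelopes."""

    coefficients: np.ndarray
    lower_fraction: float = None

    @property
    def n_states(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.coefficients.shape[1]


def build_design_matrix(path: StatePath, K: int = None) -> DesignMatrix:
    """Indicator encoding X(t, k) = 1 iff u_t = k."""
    K = path.n_states if K is None else K
    if path.states.max() >= K:
        raise ValueError("path contains states outside 0..K-1")
    X = np.zeros((path.n_samples, K))
    X[np.arange(path.n_samples), path.states] = 1.0
    return DesignMatrix(X=X, n_states=K)


def _zscore_columns(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    return (X - mu) / np.where(sd > 0, sd, 1.0), sd


def partial_correlation_maps(design: DesignMatrix, envelopes) -> PartialCorrelationMap:
    """Per-voxel multiple regression of z-scored envelopes on z-scored indicators.

    ``envelopes`` is an :class:`EnvelopeDataset` or a (V, T) array.
    States absent from the design are dropped with a warning and get NaN
    coefficients.
    """
    Y = envelopes.data if isinstance(envelopes, EnvelopeDataset) else np.asarray(envelopes, float)
    X = design.X
    T, K = X.shape
    if Y.shape[1] != T:
        raise ValueError("envelope length does not match the design matrix")
    present = np.flatnonzero(X.sum(axis=0) > 0)
    if present.size < 2:
        raise ValueError("need at least 2 distinct states present in the path")
    if present.size < K:
        absent = sorted(set(range(K)) - set(present.tolist()))
        logger.warning("states %s never occur; their maps are NaN", absent)
    Xz, _ = _zscore_columns(X[:, present])
    Yz, ysd = _zscore_columns(Y.T)
    if np.any(ysd == 0):
        logger.warning("%d constant voxels; their coefficients are NaN", int((ysd == 0).sum()))

    U, S, Vt = np.linalg.svd(Xz, full_matrices=False)
    rank = int(np.sum(S > S[0] * _RANK_TOL))
    coefs = np.full((K, Y.shape[0]), np.nan)
    if rank == present.size:
        # exact partial correlations via residualization (Frisch-Waugh)
        for idx, k in enumerate(present):
            others = np.delete(Xz, idx, axis=1)
            Q, _ = np.linalg.qr(others)
            xk = Xz[:, idx] - Q @ (Q.T @ Xz[:, idx])
            Ry = Yz - Q @ (Q.T @ Yz)
            num = xk @ Ry
            den = np.sqrt((xk @ xk) * np.einsum("tv,tv->v", Ry, Ry))
            with np.errstate(invalid="ignore", divide="ignore"):
                coefs[k] = num / den
    else:
        logger.warning(
            "indicator design is rank deficient (%d < %d): mutually exclusive "
            "exhaustive states are collinear after z-scoring; returning "
            "minimum-norm standardized GLM coefficients on the effective space",
            rank, present.size,
        )
        beta = Vt[:rank].T @ ((U[:, :rank].T @ Yz) / S[:rank, None])
        coefs[present] = beta
    coefs[:, ysd == 0] = np.nan
    return PartialCorrelationMap(coefficients=coefs)


def threshold_map(pmap: PartialCorrelationMap, lower_fraction: float) -> PartialCorrelationMap:
    """Keep, per state, only voxels with |value| >= lower_fraction * max |value|.

    Dropped voxels become NaN; signs are preserved so positive and
    negative correlations can be displayed separately.  Presentation only
    — statistics are always computed from the unthresholded map.
    """
    if not 0 <= lower_fraction <= 1:
        raise ValueError("lower_fraction must be in [0, 1]")
    C = pmap.coefficients.copy()
    for k in range(C.shape[0]):
        row = C[k]
        if np.all(np.isnan(row)):
            continue
        cut = lower_fraction * np.nanmax(np.abs(row))
        row[np.abs(row) < cut] = np.nan
    return PartialCorrelationMap(coefficients=C, lower_fraction=lower_fraction)
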