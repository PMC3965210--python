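"""Linearly constrained minimum variance (LCMV) scalar beamformer.

Projects N-channel sensor data onto single brain locations: estimate the
sensor covariance C, pick the dipole orientation that maximizes the
projected signal-to-noise ratio, form the unit-gain minimum-variance
weights

    w^T = [h^T C^-1 h]^-1 h^T C^-1,

and scale the projected time course by the projected uncorrelated sensor
noise, z(t) = w^T m(t) / sqrt(w^T w), so that source variance is
comparable across locations of different depth (lead-field norm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "SensorRecording",
    "LeadField",
    "BeamformerWeights",
    "estimate_sensor_covariance",
    "optimal_orientation",
    "beamformer_weights",
    "project_and_normalize",
    "beamform_dataset",
]


@dataclass
class SensorRecording:
    """N channels x T samples of sensor data (arbitrary field units)."""

    data: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("sensor data must be (N >= 2, T)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sensor data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass
class LeadField:
    """Sensor response (N x 3) to a unit dipole at ``location`` (mm)."""

    location: np.ndarray
    matrix: np.ndarray

    def __post_init__(self):
        self.location = np.asarray(self.location, dtype=np.float64).reshape(3)
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 3:
            raise ValueError("lead-field matrix must be (N, 3)")


@dataclass
class BeamformerWeights:
    """LCMV weights with the selected orientation; w^T h = 1 at the target."""

    weights: np.ndarray
    orientation: np.ndarray
    location: np.ndarray = None


class SingularCovarianceError(np.linalg.LinAlgError):
    pass


def estimate_sensor_covariance(recording: SensorRecording, ridge_fraction: float = 0.0) -> np.ndarray:
    """Sample covariance between all sensor pairs, with an optional diagonal ridge.

    The ridge adds ``ridge_fraction * mean(diag(C))`` to every diagonal
    entry, guaranteeing invertibility for any positive fraction.  Raises
    ``SingularCovarianceError`` if the regularized matrix is singular
    (e.g. a constant channel with ridge_fraction = 0).
    """
    if ridge_fraction < 0:
        raise ValueError("ridge_fraction must be >= 0")
    X = recording.data
    C = np.cov(X, ddof=1)
    C = 0.5 * (C + C.T)
    if ridge_fraction > 0:
        C = C + ridge_fraction * np.mean(np.diag(C)) * np.eye(C.shape[0])
    try:
        scipy.linalg.cholesky(C, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            "sensor covariance is singular; use a positive ridge_fraction"
        ) from exc
    return C


def optimal_orientation(leadfield: LeadField, C: np.ndarray) -> np.ndarray:
    """Unit dipole orientation maximizing the projected signal-to-noise ratio.

    Maximizes ``(v^T H^T C^-1 H v) / (v^T H^T C^-2 H v)`` over unit
    3-vectors v via the generalized symmetric eigenproblem.  When the top
    eigenvalue is (near-)degenerate — e.g. for C proportional to the
    identity, where the ratio is constant — the direction maximizing the
    projected signal power within the tied subspace is returned, which
    reduces to the leading right-singular vector of H for white noise.
    The sign is fixed by making the largest-magnitude component positive.
    """
    H = leadfield.matrix
    if np.linalg.matrix_rank(H) < 3:
        raise ValueError(
            f"lead field at location {leadfield.location} is rank deficient"
        )
    Ci = np.linalg.inv(C)
    A = H.T @ Ci @ H
    B = H.T @ Ci @ Ci @ H
    A = 0.5 * (A + A.T)
    B = 0.5 * (B + B.T)
    vals, vecs = scipy.linalg.eigh(A, B)
    tied = vals >= vals[-1] * (1.0 - 1e-9)
    if tied.sum() > 1:
        Q, _ = np.linalg.qr(vecs[:, tied])  # orthonormal basis of the tie
        _, sub = np.linalg.eigh(Q.T @ A @ Q)
        phi = Q @ sub[:, -1]
    else:
        phi = vecs[:, -1]
    phi = phi / np.linalg.norm(phi)
    i = np.argmax(np.abs(phi))
    if phi[i] < 0:
        phi = -phi
    return phi


def beamformer_weights(h, C, orientation=None, location=None) -> BeamformerWeights:
    """LCMV weights for a scalar lead field ``h`` (N-vector).

    ``w^T = [h^T C^-1 h]^-1 h^T C^-1`` satisfies the unit-gain constraint
    w^T h = 1.  Pass a ``LeadField`` to have the orientation selected
    automatically via :func:`optimal_orientation`.
    """
    if isinstance(h, LeadField):
        lf = h
        orientation = optimal_orientation(lf, C) if orientation is None else orientation
        location = lf.location
        h = lf.matrix @ orientation
    h = np.asarray(h, dtype=np.float64).ravel()
    if np.allclose(h, 0):
        raise ValueError("lead field is identically zero")
    Ci_h = np.linalg.solve(C, h)
    w = Ci_h / (h @ Ci_h)
    return BeamformerWeights(weights=w, orientation=orientation, location=location)


def project_and_normalize(weights: BeamformerWeights, recording: SensorRecording) -> np.ndarray:
    """Source time course z(t) = w^T m(t) / sqrt(w^T w).

    Dividing by the root of the projected sensor-noise variance w^T w
    removes the beamformer's depth bias: for white sensor noise the output
    variance is independent of the lead-field norm.
    """
    w = weights.weights
    if w.size != recording.n_channels:
        raise ValueError(
            f"weights have {w.size} channels but recording has {recording.n_channels}"
        )
    q = w @ recording.data
    return q / np.sqrt(w @ w)


def beamform_dataset(recording, leadfields, ridge_fraction: float = 0.0):
    """Project a recording through LCMV weights at every lead field.

    Returns (V, T) source time courses and the list of weights objects.
    """
    C = estimate_sensor_covariance(recording, ridge_fraction)
    out = np.empty((len(leadfields), recording.data.shape[1]))
    all_w = []
    for i, lf in enumerate(leadfields):
        bw = beamformer_weights(lf, C)
        out[i] = project_and_normalize(bw, recording)
        all_w.append(bw)
    return out, all_w
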