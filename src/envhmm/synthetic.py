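"""Generators for ground-truth Markov chains, Gaussian-HMM observations,
envelope-like voxel datasets, and toy sensor-level recordings.

These generators define the statistical structure the inference machinery
assumes: a Markov-switching state sequence with geometric dwell times,
per-state multivariate-normal emissions, and non-negative envelope data
in which each state adds its own amplitude topography on top of a
baseline.  Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EnvelopeDataset, StatePath

__all__ = [
    "GroundTruth",
    "transition_matrix_from_lifetime",
    "simulate_markov_chain",
    "simulate_gaussian_hmm",
    "simulate_envelope_dataset",
    "simulate_sensor_data",
]

_ROW_TOL = 1e-12


def _validate_transition_matrix(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(A < 0):
        raise ValueError("transition matrix has negative entries")
    row_sums = A.sum(axis=1)
    bad = np.flatnonzero(np.abs(row_sums - 1.0) > 1e-8)
    if bad.size:
        raise ValueError(
            f"transition matrix row {bad[0]} sums to {row_sums[bad[0]]:.6g}, not 1"
        )
    return A


def _validate_probs(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"{name} must be a probability vector summing to 1")
    return p


@dataclass
class GroundTruth:
    """Generative parameters of a Gaussian-observation hidden Markov model.

    ``topographies`` (K x V, non-negative amplitude gains) is used only by
    the envelope simulator and may be None for plain Gaussian-HMM fixtures.
    """

    transition_matrix: np.ndarray
    initial_probs: np.ndarray
    state_means: np.ndarray = None
    state_covs: np.ndarray = None
    topographies: np.ndarray = None
    seed: int = 0

    def __post_init__(self):
        self.transition_matrix = _validate_transition_matrix(self.transition_matrix)
        K = self.transition_matrix.shape[0]
        self.initial_probs = _validate_probs(self.initial_probs, "initial_probs")
        if self.initial_probs.size != K:
            raise ValueError("initial_probs length must match transition matrix")
        if self.state_means is not None:
            self.state_means = np.atleast_2d(np.asarray(self.state_means, float))
            self.state_covs = np.asarray(self.state_covs, dtype=np.float64)
            if self.state_means.shape[0] != K or self.state_covs.shape[0] != K:
                raise ValueError("need one mean and one covariance per state")
            for k, S in enumerate(self.state_covs):
                if not np.allclose(S, S.T, atol=1e-10):
                    raise ValueError(f"covariance of state {k} is not symmetric")
                if np.linalg.eigvalsh(S).min() < -1e-10:
                    raise ValueError(f"covariance of state {k} is not positive semi-definite")
        if self.topographies is not None:
            self.topographies = np.asarray(self.topographies, dtype=np.float64)
            if np.any(self.topographies < 0):
                raise ValueError("topographies must be non-negative")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def stationary_distribution(self) -> np.ndarray:
        """Leading left eigenvector of the transition matrix, normalized."""
        vals, vecs = np.linalg.eig(self.transition_matrix.T)
        i = np.argmin(np.abs(vals - 1.0))
        pi = np.real(vecs[:, i])
        return pi / pi.sum()


def transition_matrix_from_lifetime(
    n_states: int,
    mean_lifetime_samples: float,
    relative_occupancy=None,
) -> np.ndarray:
    """Row-stochastic matrix with geometric dwell times of the given mean.

    The self-transition probability is ``p = 1 - 1/mean_lifetime_samples``
    (a geometric dwell distribution with mean ``mean_lifetime_samples``);
    the leaving mass ``1 - p`` is split over the other states proportional
    to ``relative_occupancy`` (uniform if None), which skews the chain's
    stationary distribution towards the heavier states.
    """
    if mean_lifetime_samples < 1:
        raise ValueError("mean_lifetime_samples must be >= 1")
    p_stay = 1.0 - 1.0 / mean_lifetime_samples
    if relative_occupancy is None:
        w = np.ones(n_states)
    else:
        w = np.asarray(relative_occupancy, dtype=np.float64)
        if w.size != n_states or np.any(w <= 0):
            raise ValueError("relative_occupancy must be positive, one entry per state")
    A = np.zeros((n_states, n_states))
    for i in range(n_states):
        others = np.delete(np.arange(n_states), i)
        A[i, others] = (1.0 - p_stay) * w[others] / w[others].sum()
        A[i, i] = p_stay
    if n_states == 1:
        A[0, 0] = 1.0
    return A


def simulate_markov_chain(
    initial_probs,
    transition_matrix,
    n_samples: int,
    seed,
    sampling_rate: float = 1.0,
) -> StatePath:
    """Draw a first-order Markov state sequence.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    A = _validate_transition_matrix(transition_matrix)
    pi0 = _validate_probs(initial_probs, "initial_probs")
    if pi0.size != A.shape[0]:
        raise ValueError("initial_probs length must match transition matrix")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    cum_rows = np.cumsum(A, axis=1)
    u = rng.random(n_samples)
    states = np.empty(n_samples, dtype=np.int64)
    states[0] = np.searchsorted(np.cumsum(pi0), u[0], side="right")
    for t in range(1, n_samples):
        states[t] = np.searchsorted(cum_rows[states[t - 1]], u[t], side="right")
    np.clip(states, 0, A.shape[0] - 1, out=states)
    return StatePath(states, sampling_rate, n_states=A.shape[0])


def _psd_factor(S: np.ndarray) -> np.ndarray:
    """Square-root factor of a PSD matrix (tolerates zero eigenvalues)."""
    vals, vecs = np.linalg.eigh(S)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def simulate_gaussian_hmm(
    ground_truth: GroundTruth,
    n_samples: int,
    seed,
    sampling_rate: float = 1.0,
) -> tuple[np.ndarray, StatePath]:
    """Observations (n_samples x M) drawn from the Gaussian of the active state."""
    gt = ground_truth
    if gt.state_means is None:
        raise ValueError("GroundTruth must carry state_means and state_covs")
    rng = np.random.default_rng(seed)
    path = simulate_markov_chain(
        gt.initial_probs, gt.transition_matrix, n_samples, rng, sampling_rate
    )
    M = gt.state_means.shape[1]
    z = rng.standard_normal((n_samples, M))
    obs = np.empty((n_samples, M))
    for k in range(gt.n_states):
        idx = path.states == k
        L = _psd_factor(gt.state_covs[k])
        obs[idx] = gt.state_means[k] + z[idx] @ L.T
    return obs, path


def simulate_envelope_dataset(
    topographies,
    baseline_level: float,
    mean_lifetime_samples: float,
    n_subjects: int,
    samples_per_subject: int,
    noise_sd: float,
    seed,
    sampling_rate: float = 40.0,
    relative_occupancy=None,
    voxel_coords=None,
) -> tuple[EnvelopeDataset, StatePath]:
    """Non-negative envelope-like voxel data with embedded state topographies.

    Each voxel's value is ``baseline + topographies[u_t, v] + noise``,
    rectified at zero.  Dwell times are geometric with the requested mean;
    each subject's chain restarts independently from the stationary
    distribution, and segment boundaries are recorded.  Returns the
    dataset together with the true state path.
    """
    topographies = np.asarray(topographies, dtype=np.float64)
    if topographies.ndim != 2:
        raise ValueError("topographies must be (K, V)")
    if np.any(topographies < 0):
        raise ValueError("topographies must be non-negative")
    if baseline_level <= 0:
        raise ValueError("baseline_level must be positive")
    K, V = topographies.shape
    A = transition_matrix_from_lifetime(K, mean_lifetime_samples, relative_occupancy)
    gt = GroundTruth(A, np.ones(K) / K)
    pi0 = gt.stationary_distribution()
    rng = np.random.default_rng(seed)

    blocks, paths = [], []
    for _ in range(n_subjects):
        path = simulate_markov_chain(pi0, A, samples_per_subject, rng, sampling_rate)
        data = baseline_level + topographies[path.states].T  # (V, T_subject)
        if noise_sd > 0:
            data = data + noise_sd * rng.standard_normal(data.shape)
        blocks.append(np.maximum(data, 0.0))
        paths.append(path.states)
    boundaries = np.cumsum([samples_per_subject] * n_subjects)
    dataset = EnvelopeDataset(
        np.concatenate(blocks, axis=1),
        sampling_rate,
        voxel_coords=voxel_coords,
        segment_boundaries=boundaries,
    )
    full_path = StatePath(
        np.concatenate(paths), sampling_rate, segment_boundaries=boundaries, n_states=K
    )
    return dataset, full_path


def simulate_sensor_data(
    leadfields,
    orientations,
    dipole_timecourses,
    noise_sd: float,
    seed,
    sampling_rate: float = 200.0,
):
    """Sensor time series ``m(t) = sum_r H_r phi_r s_r(t) + noise``.

    Parameters
    ----------
    leadfields : sequence of (N, 3) lead-field matrices, one per dipole.
    orientations : sequence of 3-vectors (need not be unit length).
    dipole_timecourses : sequence of (T,) source amplitude series.
    noise_sd : standard deviation of i.i.d. Gaussian sensor noise.

    Returns an (N, T) array.  The noise draw depends only on ``seed`` and
    the array shape, so two-dipole output equals the sum of the two
    single-dipole signal parts plus the same noise.
    """
    leadfields = [np.asarray(H, dtype=np.float64) for H in leadfields]
    if not leadfields:
        raise ValueError("need at least one lead field")
    N = leadfields[0].shape[0]
    tcs = [np.asarray(s, dtype=np.float64) for s in dipole_timecourses]
    T = tcs[0].size
    if not (len(leadfields) == len(orientations) == len(tcs)):
        raise ValueError("leadfields, orientations and timecourses must align")
    m = np.zeros((N, T))
    for H, phi, s in zip(leadfields, orientations, tcs):
        if H.shape != (N, 3):
            raise ValueError("each lead field must be (N, 3)")
        if s.size != T:
            raise ValueError("all dipole time courses must have equal length")
        h = H @ np.asarray(phi, dtype=np.float64)
        m += np.outer(h, s)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        m = m + noise_sd * rng.standard_normal((N, T))
    return m
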