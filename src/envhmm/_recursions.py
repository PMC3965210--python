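"""Scaled forward-backward and Viterbi recursions (numba kernels).

The recursions run independently within each segment (subject block),
restarting from the initial-state distribution, and use per-sample
rescaling so they remain stable for sequences up to millions of samples.
Inputs are the *expected* log parameters of the variational posterior
(subnormalized once exponentiated, which the scaling absorbs).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["forward_backward", "viterbi_path"]


@njit(cache=False)
def _forward_backward_kernel(B, shifts, At, pit, bounds):
    T, K = B.shape
    gamma = np.empty((T, K))
    xi = np.zeros((K, K))
    first = np.zeros(K)
    alpha = np.empty((T, K))
    c = np.empty(T)
    ln_z = 0.0
    start = 0
    for s in range(bounds.shape[0]):
        stop = bounds[s]
        # forward pass with per-sample scaling
        tot = 0.0
        for k in range(K):
            alpha[start, k] = pit[k] * B[start, k]
            tot += alpha[start, k]
        c[start] = tot
        for k in range(K):
            alpha[start, k] /= tot
        for t in range(start + 1, stop):
            tot = 0.0
            for j in range(K):
                acc = 0.0
                for i in range(K):
                    acc += alpha[t - 1, i] * At[i, j]
                alpha[t, j] = acc * B[t, j]
                tot += alpha[t, j]
            c[t] = tot
            for j in range(K):
                alpha[t, j] /= tot
        # backward pass; gamma and accumulated xi
        beta = np.ones(K)
        for k in range(K):
            gamma[stop - 1, k] = alpha[stop - 1, k]
        for t in range(stop - 2, start - 1, -1):
            bb = np.empty(K)
            for j in range(K):
                bb[j] = B[t + 1, j] * beta[j]
            new_beta = np.empty(K)
            for i in range(K):
                acc = 0.0
                for j in range(K):
                    acc += At[i, j] * bb[j]
                new_beta[i] = acc / c[t + 1]
            for i in range(K):
                for j in range(K):
                    xi[i, j] += alpha[t, i] * At[i, j] * bb[j] / c[t + 1]
            for i in range(K):
                beta[i] = new_beta[i]
                gamma[t, i] = alpha[t, i] * beta[i]
            # renormalize against drift
            g = 0.0
            for i in range(K):
                g += gamma[t, i]
            for i in range(K):
                gamma[t, i] /= g
        for k in range(K):
            first[k] += gamma[start, k]
        for t in range(start, stop):
            ln_z += np.log(c[t]) + shifts[t]
        start = stop
    return gamma, xi, first, ln_z


def forward_backward(log_b, log_a, log_pi, boundaries):
    """Marginals, expected transition counts and log normalizer.

    Parameters
    ----------
    log_b : (T, K) expected log emission densities.
    log_a : (K, K) expected log transition probabilities.
    log_pi : (K,) expected log initial-state probabilities.
    boundaries : segment end indices.

    Returns
    -------
    gamma : (T, K) posterior state marginals (rows sum to 1).
    xi : (K, K) expected transition counts summed over within-segment pairs.
    first : (K,) summed marginals at segment starts.
    ln_z : log normalizer of the chain posterior.
    """
    log_b = np.ascontiguousarray(log_b, dtype=np.float64)
    shifts = log_b.max(axis=1)
    B = np.exp(log_b - shifts[:, None])
    At = np.exp(np.asarray(log_a, dtype=np.float64))
    pit = np.exp(np.asarray(log_pi, dtype=np.float64))
    bounds = np.ascontiguousarray(boundaries, dtype=np.int64)
    return _forward_backward_kernel(B, shifts, At, pit, bounds)


@njit(cache=False)
def _viterbi_kernel(logB, logA, logpi, bounds):
    T, K = logB.shape
    path = np.empty(T, dtype=np.int64)
    delta = np.empty((T, K))
    psi = np.empty((T, K), dtype=np.int64)
    start = 0
    for s in range(bounds.shape[0]):
        stop = bounds[s]
        for k in range(K):
            delta[start, k] = logpi[k] + logB[start, k]
            psi[start, k] = 0
        for t in range(start + 1, stop):
            for j in range(K):
                best = delta[t - 1, 0] + logA[0, j]
                arg = 0
                for i in range(1, K):
                    v = delta[t - 1, i] + logA[i, j]
                    if v > best:  # strict: ties keep the lowest index
                        best = v
                        arg = i
                delta[t, j] = best + logB[t, j]
                psi[t, j] = arg
        best = delta[stop - 1, 0]
        arg = 0
        for k in range(1, K):
            if delta[stop - 1, k] > best:
                best = delta[stop - 1, k]
                arg = k
        path[stop - 1] = arg
        for t in range(stop - 2, start - 1, -1):
            path[t] = psi[t + 1, path[t + 1]]
        start = stop
    return path


def viterbi_path(log_b, log_a, log_pi, boundaries):
    """Most probable joint state path per segment (ties -> lowest index)."""
    log_b = np.ascontiguousarray(log_b, dtype=np.float64)
    bounds = np.ascontiguousarray(boundaries, dtype=np.int64)
    return _viterbi_kernel(
        log_b,
        np.ascontiguousarray(log_a, dtype=np.float64),
        np.ascontiguousarray(log_pi, dtype=np.float64),
        bounds,
    )
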