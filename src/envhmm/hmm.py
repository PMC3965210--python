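"""Variational-Bayes inference for the Gaussian-observation hidden Markov model.

The model: a first-order Markov chain over K mutually exclusive states
with a Dirichlet prior on each transition row and on the initial-state
distribution, and a multivariate-normal observation model per state,
theta_k = {mu_k, Sigma_k}, with a conjugate Gaussian-Wishart prior.  The
factorized variational posterior q(s) q(pi_0) q(pi) prod_k q(mu_k, Lambda_k)
is optimized by coordinate ascent (E-step: forward-backward under the
expected log parameters; M-step: conjugate hyperparameter updates), and
the variational free energy

    F = -ln Z_tilde + KL(q(parameters) || p(parameters))

decreases monotonically; -F approximates the log model evidence and is
used to select among restarts and model orders.

Data are typically reduced to M principal components with unit variance
and zero mean (``pca_whiten``) before inference; spatial interpretation
is recovered afterwards from the full-rank envelopes (``spatial_maps``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, multigammaln

from ._recursions import forward_backward, viterbi_path
from .containers import EnvelopeDataset, StatePath, as_segment_boundaries

__all__ = [
    "WhitenedData",
    "HMMPriors",
    "HMMModel",
    "StatePosterior",
    "pca_whiten",
    "init_model",
    "vb_e_step",
    "vb_m_step",
    "free_energy",
    "fit_hmm",
    "viterbi_decode",
    "model_order_sweep",
    "expected_log_parameters",
    "align_states",
]

logger = logging.getLogger(__name__)

LOG2PI = np.log(2.0 * np.pi)


# --------------------------------------------------------------------------
# whitening
# --------------------------------------------------------------------------

@dataclass
class WhitenedData:
    """Unit-variance, zero-mean principal-component scores of the envelopes.

    ``scores`` is (T, M); ``transform`` is the (V, M) back-projection such
    that ``transform @ scores.T + mean[:, None]`` reconstructs the input
    (exactly when M equals the rank).  ``component_variances`` are the
    variances of the components before scaling to unit variance.
    """

    scores: np.ndarray
    transform: np.ndarray
    mean: np.ndarray
    component_variances: np.ndarray
    sampling_rate: float = None
    segment_boundaries: np.ndarray = None

    def __post_init__(self):
        self.segment_boundaries = as_segment_boundaries(
            self.segment_boundaries, self.scores.shape[0]
        )

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca_whiten(group_envelopes, n_components: int) -> WhitenedData:
    """Reduce (V, T) group envelopes to unit-variance principal components.

    Accepts an :class:`EnvelopeDataset` or a plain (V, T) array.  The sign
    of each component is fixed by making its largest-magnitude spatial
    loading positive, so the decomposition is reproducible.
    """
    if isinstance(group_envelopes, EnvelopeDataset):
        X = group_envelopes.data
        rate = group_envelopes.sampling_rate
        bounds = group_envelopes.segment_boundaries
    else:
        X = np.asarray(group_envelopes, dtype=np.float64)
        rate = None
        bounds = None
    V, T = X.shape
    mean = X.mean(axis=1)
    Y = (X - mean[:, None]).T  # (T, V), zero-mean columns
    U, S, Vt = np.linalg.svd(Y, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-10)) if S.size else 0
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds the data rank ({rank})"
        )
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    # deterministic sign: largest-|loading| voxel of each component positive
    loadings = Vt.T * S / np.sqrt(T)  # (V, M)
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    scores = U * np.sqrt(T) * flip
    transform = loadings * flip
    return WhitenedData(
        scores=scores,
        transform=transform,
        mean=mean,
        component_variances=S**2 / T,
        sampling_rate=rate,
        segment_boundaries=bounds,
    )


# --------------------------------------------------------------------------
# model containers
# --------------------------------------------------------------------------

@dataclass
class HMMPriors:
    """Broad conjugate priors for the VB-HMM.

    transition_alpha / initial_alpha : symmetric Dirichlet concentrations.
    beta : mean-precision scale of the Gaussian-Wishart (small = broad).
    mean : prior mean vector (defaults to 0).
    scale_inv : inverse scale matrix W0^-1 of the Wishart (defaults to M*I,
        i.e. E[Lambda] = nu0 * W0 = I at nu0 = M, matched to unit-variance
        whitened data).
    dof : Wishart degrees of freedom (defaults to M, the minimum).
    """

    transition_alpha: float = 1.0
    initial_alpha: float = 1.0
    beta: float = 1e-3
    mean: np.ndarray = None
    scale_inv: np.ndarray = None
    dof: float = None

    def resolved(self, M: int) -> "HMMPriors":
        return HMMPriors(
            transition_alpha=self.transition_alpha,
            initial_alpha=self.initial_alpha,
            beta=self.beta,
            mean=np.zeros(M) if self.mean is None else np.asarray(self.mean, float),
            scale_inv=(M * np.eye(M)) if self.scale_inv is None
            else np.asarray(self.scale_inv, float),
            dof=float(M) if self.dof is None else float(self.dof),
        )


@dataclass
class HMMModel:
    """Posterior (and prior) hyperparameters of a K-state VB-HMM.

    Transition rows and the initial distribution carry Dirichlet
    posteriors (``trans_alpha``, ``init_alpha``); each state carries a
    Gaussian-Wishart posterior (``beta``, ``m``, ``W``, ``nu``), where
    ``W`` is the Wishart scale matrix, so E[Lambda_k] = nu_k W_k.
    """

    n_states: int
    n_features: int
    priors: HMMPriors
    trans_alpha: np.ndarray
    init_alpha: np.ndarray
    beta: np.ndarray
    m: np.ndarray
    W: np.ndarray
    nu: np.ndarray

    # ---- expected parameters -------------------------------------------
    def expected_transition_matrix(self) -> np.ndarray:
        return self.trans_alpha / self.trans_alpha.sum(axis=1, keepdims=True)

    def expected_initial_probs(self) -> np.ndarray:
        return self.init_alpha / self.init_alpha.sum()

    def expected_log_transition(self) -> np.ndarray:
        return digamma(self.trans_alpha) - digamma(
            self.trans_alpha.sum(axis=1, keepdims=True)
        )

    def expected_log_initial(self) -> np.ndarray:
        return digamma(self.init_alpha) - digamma(self.init_alpha.sum())

    def expected_means(self) -> np.ndarray:
        return self.m.copy()

    def expected_covariances(self) -> np.ndarray:
        """Posterior mean of Sigma_k = (W_k^-1) / (nu_k - M - 1) when defined,
        otherwise the inverse expected precision (nu_k W_k)^-1."""
        M = self.n_features
        covs = np.empty_like(self.W)
        for k in range(self.n_states):
            Winv = np.linalg.inv(self.W[k])
            if self.nu[k] > M + 1:
                covs[k] = Winv / (self.nu[k] - M - 1)
            else:
                covs[k] = Winv / self.nu[k]
        return covs

    def expected_log_det_precision(self) -> np.ndarray:
        M = self.n_features
        out = np.empty(self.n_states)
        for k in range(self.n_states):
            sign, logdet = np.linalg.slogdet(self.W[k])
            if sign <= 0:
                raise np.linalg.LinAlgError("Wishart scale matrix is not PD")
            out[k] = (
                digamma(0.5 * (self.nu[k] - np.arange(M))).sum()
                + M * np.log(2.0)
                + logdet
            )
        return out

    def expected_log_emissions(self, Y: np.ndarray) -> np.ndarray:
        """(T, K) matrix of E_q[ln N(y_t | mu_k, Lambda_k^-1)]."""
        T, M = Y.shape
        logdet = self.expected_log_det_precision()
        out = np.empty((T, K := self.n_states))
        for k in range(K):
            D = Y - self.m[k]
            quad = self.nu[k] * np.einsum("ti,ij,tj->t", D, self.W[k], D)
            out[:, k] = 0.5 * (logdet[k] - M * LOG2PI - M / self.beta[k] - quad)
        return out


@dataclass
class StatePosterior:
    """VB E-step output: state marginals and transition statistics.

    gamma : (T, K) marginal posteriors P(s_t = k | y); rows sum to 1.
    xi : (K, K) expected transition counts summed within segments.
    initial_counts : (K,) summed marginals at segment starts.
    log_evidence : ln Z_tilde, the chain's log normalizer under the
        expected log parameters.
    free_energy_trace : per-iteration free energies (filled by fit_hmm).
    """

    gamma: np.ndarray
    xi: np.ndarray
    initial_counts: np.ndarray
    log_evidence: float
    free_energy_trace: list = field(default_factory=list)


def expected_log_parameters(model: HMMModel, Y: np.ndarray):
    """(log_pi, log_A, log_B): the expected log parameters the E-step uses."""
    return (
        model.expected_log_initial(),
        model.expected_log_transition(),
        model.expected_log_emissions(Y),
    )


# --------------------------------------------------------------------------
# VB steps
# --------------------------------------------------------------------------

def _scores_and_bounds(data, segment_boundaries=None):
    if isinstance(data, WhitenedData):
        Y = data.scores
        if segment_boundaries is None:
            bounds = data.segment_boundaries
        else:
            bounds = as_segment_boundaries(segment_boundaries, Y.shape[0])
    else:
        Y = np.asarray(data, dtype=np.float64)
        if Y.ndim != 2:
            raise ValueError("observations must be a (T, M) array")
        bounds = as_segment_boundaries(segment_boundaries, Y.shape[0])
    return Y, bounds


def vb_e_step(model: HMMModel, data, segment_boundaries=None) -> StatePosterior:
    """Forward-backward under the expected log parameters.

    Chains restart with the initial-state distribution at every segment
    boundary; no transition is counted across a boundary.
    """
    Y, bounds = _scores_and_bounds(data, segment_boundaries)
    log_pi, log_a, log_b = expected_log_parameters(model, Y)
    gamma, xi, first, ln_z = forward_backward(log_b, log_a, log_pi, bounds)
    return StatePosterior(gamma=gamma, xi=xi, initial_counts=first, log_evidence=ln_z)


def vb_m_step(posterior: StatePosterior, data, model: HMMModel) -> HMMModel:
    """Conjugate hyperparameter updates from the E-step responsibilities."""
    Y, _ = _scores_and_bounds(data)
    K, M = model.n_states, model.n_features
    pri = model.priors
    trans_alpha = pri.transition_alpha + posterior.xi
    init_alpha = pri.initial_alpha + posterior.initial_counts

    Nk = posterior.gamma.sum(axis=0)
    beta = pri.beta + Nk
    nu = pri.dof + Nk
    m = np.empty((K, M))
    W = np.empty((K, M, M))
    for k in range(K):
        if Nk[k] > 0:
            ybar = posterior.gamma[:, k] @ Y / Nk[k]
        else:
            ybar = np.zeros(M)
        D = Y - ybar
        scatter = (D * posterior.gamma[:, k, None]).T @ D
        m[k] = (pri.beta * pri.mean + Nk[k] * ybar) / beta[k]
        dm = ybar - pri.mean
        W_inv = (
            pri.scale_inv
            + scatter
            + (pri.beta * Nk[k] / beta[k]) * np.outer(dm, dm)
        )
        W[k] = np.linalg.inv(0.5 * (W_inv + W_inv.T))
    return replace(
        model, trans_alpha=trans_alpha, init_alpha=init_alpha,
        beta=beta, m=m, W=W, nu=nu,
    )


def _kl_dirichlet(alpha_q: np.ndarray, alpha_p: np.ndarray) -> float:
    aq0, ap0 = alpha_q.sum(), alpha_p.sum()
    return float(
        gammaln(aq0) - gammaln(ap0)
        - np.sum(gammaln(alpha_q) - gammaln(alpha_p))
        + np.sum((alpha_q - alpha_p) * (digamma(alpha_q) - digamma(aq0)))
    )


def _log_wishart_b(W: np.ndarray, nu: float) -> float:
    M = W.shape[0]
    sign, logdet = np.linalg.slogdet(W)
    return float(-0.5 * nu * logdet - 0.5 * nu * M * np.log(2.0) - multigammaln(0.5 * nu, M))


def _kl_gaussian_wishart(model: HMMModel, k: int) -> float:
    """KL of state k's Gaussian-Wishart posterior from its prior."""
    pri = model.priors
    M = model.n_features
    nu_q, W_q = model.nu[k], model.W[k]
    W_p = np.linalg.inv(pri.scale_inv)
    nu_p = pri.dof
    e_logdet = model.expected_log_det_precision()[k]
    tr = np.trace(pri.scale_inv @ W_q)
    kl_wishart = (
        _log_wishart_b(W_q, nu_q) - _log_wishart_b(W_p, nu_p)
        + 0.5 * (nu_q - nu_p) * e_logdet
        + 0.5 * nu_q * tr
        - 0.5 * nu_q * M
    )
    dm = model.m[k] - pri.mean
    kl_gauss = 0.5 * (
        M * np.log(model.beta[k] / pri.beta)
        - M
        + M * pri.beta / model.beta[k]
        + pri.beta * nu_q * dm @ W_q @ dm
    )
    return float(kl_wishart + kl_gauss)


def free_energy(model: HMMModel, posterior: StatePosterior, data=None) -> float:
    """Variational free energy F = -ln Z_tilde + KL(q(Theta) || p(Theta)).

    Lower is better; -F approximates the log model evidence.  The
    ``posterior`` must come from an E-step under this ``model``.
    """
    pri = model.priors
    K = model.n_states
    kl = _kl_dirichlet(
        model.init_alpha, np.full(K, pri.initial_alpha)
    )
    prior_row = np.full(K, pri.transition_alpha)
    for i in range(K):
        kl += _kl_dirichlet(model.trans_alpha[i], prior_row)
    for k in range(K):
        kl += _kl_gaussian_wishart(model, k)
    return float(-posterior.log_evidence + kl)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def init_model(K: int, M: int, priors: HMMPriors = None) -> HMMModel:
    """Model with posteriors initialized at the priors."""
    pri = (priors or HMMPriors()).resolved(M)
    return HMMModel(
        n_states=K,
        n_features=M,
        priors=pri,
        trans_alpha=np.full((K, K), pri.transition_alpha),
        init_alpha=np.full(K, pri.initial_alpha),
        beta=np.full(K, pri.beta),
        m=np.tile(pri.mean, (K, 1)),
        W=np.tile(np.linalg.inv(pri.scale_inv), (K, 1, 1)),
        nu=np.full(K, pri.dof),
    )


def _random_start(Y, bounds, K, priors, rng) -> HMMModel:
    """Randomly initialized model for one restart.

    Responsibilities drawn independently from a symmetric Dirichlet
    average out over long sequences (every state's weighted moments
    approach the global moments), leaving VB stuck at the symmetric
    saddle point where all states are identical.  Symmetry is therefore
    broken in parameter space instead: each state's posterior mean is a
    randomly drawn observation, with the global precision as the initial
    expected precision of every state.
    """
    T, M = Y.shape
    model = init_model(K, M, priors)
    idx = rng.choice(T, size=K, replace=False)
    model.m = Y[idx].copy()
    model.beta = np.full(K, 1.0)
    cov = np.cov(Y.T, ddof=0) + 1e-8 * np.eye(M)
    nu0 = float(M + 2)
    model.nu = np.full(K, nu0)
    model.W = np.tile(np.linalg.inv(cov) / nu0, (K, 1, 1))  # E[Lambda] = cov^-1
    return model


def fit_hmm(
    data,
    K: int,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-5,
    seed=0,
    priors: HMMPriors = None,
    segment_boundaries=None,
) -> tuple[HMMModel, StatePosterior]:
    """Fit a K-state VB-HMM; return the restart with the lowest free energy.

    Each restart starts from random responsibilities (symmetric Dirichlet)
    followed by an M-step, then alternates E- and M-steps until the
    relative free-energy change drops below ``tol`` or ``max_iter``
    iterations.  ``data`` is a :class:`WhitenedData` or a (T, M) array.
    """
    if K < 1 or n_restarts < 1:
        raise ValueError("K and n_restarts must be >= 1")
    Y, bounds = _scores_and_bounds(data, segment_boundaries)
    if np.any(Y.var(axis=0) <= 0):
        raise ValueError("degenerate data: a component has zero variance")
    seeds = np.random.SeedSequence(seed).spawn(n_restarts)
    best = None
    for r, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        model = _random_start(Y, bounds, K, priors, rng)
        trace = []
        post = None
        for _ in range(max_iter):
            post = vb_e_step(model, Y, bounds)
            f = free_energy(model, post)
            trace.append(f)
            if len(trace) > 1 and abs(trace[-2] - trace[-1]) < tol * abs(trace[-2]):
                break
            model = vb_m_step(post, Y, model)
        post.free_energy_trace = trace
        logger.info("restart %d: F = %.6f after %d iterations", r, trace[-1], len(trace))
        if best is None or trace[-1] < best[0]:
            best = (trace[-1], model, post)
    return best[1], best[2]


def viterbi_decode(model: HMMModel, data, segment_boundaries=None) -> StatePath:
    """Most probable joint path under the expected log parameters."""
    Y, bounds = _scores_and_bounds(data, segment_boundaries)
    log_pi, log_a, log_b = expected_log_parameters(model, Y)
    path = viterbi_path(log_b, log_a, log_pi, bounds)
    rate = data.sampling_rate if isinstance(data, WhitenedData) and data.sampling_rate else 1.0
    return StatePath(path, rate, segment_boundaries=bounds, n_states=model.n_states)


def model_order_sweep(
    data,
    K_list,
    n_restarts: int = 10,
    seed=0,
    segment_boundaries=None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit one HMM per model order and tabulate selection metrics.

    Returns a DataFrame with columns ``n_states``, ``free_energy``,
    ``min_fractional_occupancy`` and ``mean_life_time`` (seconds),
    computed from each fit's Viterbi path.
    """
    from . import state_stats

    rows = []
    for K in K_list:
        model, post = fit_hmm(
            data, K, n_restarts=n_restarts, seed=seed,
            segment_boundaries=segment_boundaries, **fit_kwargs,
        )
        path = viterbi_decode(model, data, segment_boundaries)
        fo = state_stats.fractional_occupancy(path)
        lifetimes = [
            state_stats.mean_life_time(path, k)
            for k in range(K)
            if state_stats.number_of_occurrences(path, k) > 0
        ]
        rows.append(
            {
                "n_states": K,
                "free_energy": post.free_energy_trace[-1],
                "min_fractional_occupancy": float(fo.min()),
                "mean_life_time": float(np.mean(lifetimes)),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# label alignment
# --------------------------------------------------------------------------

def align_states(estimated_means: np.ndarray, reference_means: np.ndarray) -> np.ndarray:
    """Permutation mapping estimated labels onto reference labels.

    Maximizes the summed Pearson correlation between matched state mean
    vectors (Hungarian assignment).  ``perm[j]`` is the estimated state
    matched to reference state ``j``.
    """
    from scipy.optimize import linear_sum_assignment

    K = reference_means.shape[0]
    cost = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            a, b = estimated_means[i], reference_means[j]
            sa, sb = a.std(), b.std()
            if sa > 0 and sb > 0:
                cost[i, j] = -np.corrcoef(a, b)[0, 1]
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(K, dtype=np.int64)
    perm[cols] = rows
    return perm
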