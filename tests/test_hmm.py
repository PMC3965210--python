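"""VB-HMM machinery: whitening, E/M steps, free energy, decoding, sweeps."""

import itertools

import numpy as np
import pytest
from scipy.special import multigammaln

from envhmm import hmm, state_stats, synthetic


def enumerate_posterior(model, Y, boundaries=None):
    """Exhaustive-path oracle: exact marginals, log evidence and best path
    under the model's expected log parameters."""
    T, _ = Y.shape
    K = model.n_states
    log_pi, log_a, log_b = hmm.expected_log_parameters(model, Y)
    bounds = [T] if boundaries is None else list(boundaries)
    gamma = np.zeros((T, K))
    lnz = 0.0
    best_path = np.empty(T, dtype=int)
    start = 0
    for stop in bounds:
        seg = range(start, stop)
        paths = list(itertools.product(range(K), repeat=stop - start))
        lps = np.empty(len(paths))
        for i, p in enumerate(paths):
            lp = log_pi[p[0]] + log_b[start, p[0]]
            for j, t in enumerate(seg):
                if j:
                    lp += log_a[p[j - 1], p[j]] + log_b[t, p[j]]
            lps[i] = lp
        shift = lps.max()
        w = np.exp(lps - shift)
        lnz += np.log(w.sum()) + shift
        w /= w.sum()
        for p, wi in zip(paths, w):
            for j, t in enumerate(seg):
                gamma[t, p[j]] += wi
        best_path[start:stop] = paths[int(np.argmax(lps))]
        start = stop
    return gamma, lnz, best_path


def arbitrary_model(K, M, seed):
    """A non-trivial model obtained by a few VB iterations on random data."""
    rng = np.random.default_rng(seed)
    Y = rng.normal(size=(80, M))
    model, _ = hmm.fit_hmm(Y, K, n_restarts=1, max_iter=4, seed=seed)
    return model


class TestPcaWhiten:
    def test_rank2_reconstruction(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 6))
        X = (rng.normal(size=(200, 2)) @ basis).T  # (V=6, T=200), rank 2
        white = hmm.pca_whiten(X, 2)
        recon = white.transform @ white.scores.T + white.mean[:, None]
        assert np.abs(recon - X).max() < 1e-8

    def test_scores_have_identity_covariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 500))
        white = hmm.pca_whiten(X, 5)
        cov = np.cov(white.scores.T, ddof=0)
        assert np.abs(cov - np.eye(5)).max() < 1e-6
        assert np.abs(white.scores.mean(axis=0)).max() < 1e-8

    def test_components_beyond_rank_rejected(self):
        rng = np.random.default_rng(2)
        basis = rng.normal(size=(3, 8))
        X = (rng.normal(size=(100, 3)) @ basis).T
        with pytest.raises(ValueError, match="rank"):
            hmm.pca_whiten(X, 4)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 300))
        a = hmm.pca_whiten(X, 4)
        b = hmm.pca_whiten(X.copy(), 4)
        assert np.array_equal(a.scores, b.scores)
        for k in range(4):
            i = np.argmax(np.abs(a.transform[:, k]))
            assert a.transform[i, k] > 0


class TestEStep:
    def test_single_state_gamma_is_one(self):
        model = arbitrary_model(1, 2, seed=5)
        Y = np.random.default_rng(5).normal(size=(40, 2))
        post = hmm.vb_e_step(model, Y)
        assert np.allclose(post.gamma, 1.0)

    def test_matches_exhaustive_enumeration(self):
        model = arbitrary_model(2, 2, seed=6)
        Y = np.random.default_rng(6).normal(size=(6, 2))
        gamma, lnz, _ = enumerate_posterior(model, Y)
        post = hmm.vb_e_step(model, Y)
        assert np.abs(post.gamma - gamma).max() < 1e-10
        assert post.log_evidence == pytest.approx(lnz, abs=1e-10)

    def test_segmented_chain_restarts(self):
        model = arbitrary_model(2, 2, seed=7)
        Y = np.random.default_rng(7).normal(size=(8, 2))
        bounds = [4, 8]
        gamma, lnz, _ = enumerate_posterior(model, Y, bounds)
        post = hmm.vb_e_step(model, Y, segment_boundaries=bounds)
        assert np.abs(post.gamma - gamma).max() < 1e-10
        # expected transition counts cover only within-segment pairs
        assert post.xi.sum() == pytest.approx(8 - 2, abs=1e-8)

    def test_label_permutation_symmetry(self):
        from dataclasses import replace

        model = arbitrary_model(3, 2, seed=8)
        Y = np.random.default_rng(8).normal(size=(30, 2))
        perm = np.array([2, 0, 1])
        permuted = replace(
            model,
            trans_alpha=model.trans_alpha[np.ix_(perm, perm)],
            init_alpha=model.init_alpha[perm],
            beta=model.beta[perm],
            m=model.m[perm],
            W=model.W[perm],
            nu=model.nu[perm],
        )
        a = hmm.vb_e_step(model, Y)
        b = hmm.vb_e_step(permuted, Y)
        assert np.allclose(a.gamma[:, perm], b.gamma, atol=1e-12)


class TestMStep:
    def test_dirichlet_update_by_hand(self):
        """Three samples, two states, hand-set responsibilities."""
        model = hmm.init_model(2, 1)
        Y = np.array([[0.0], [1.0], [2.0]])
        gamma = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]])
        xi = np.array([[0.4, 0.6], [0.1, 0.9]])
        post = hmm.StatePosterior(gamma, xi, gamma[[0]].sum(0), 0.0)
        new = hmm.vb_m_step(post, Y, model)
        # prior concentration 1 plus the summed expected counts
        assert np.allclose(new.trans_alpha, 1.0 + xi)
        assert np.allclose(new.init_alpha, [2.0, 1.0])
        # Gaussian-Wishart: beta = beta0 + N_k, nu = nu0 + N_k,
        # m = (beta0*m0 + N_k*ybar_k) / beta  with ybar_0 = (1*0+0.5*1)/1.5
        assert np.allclose(new.beta, [1e-3 + 1.5, 1e-3 + 1.5])
        assert np.allclose(new.nu, [1 + 1.5, 1 + 1.5])
        assert new.m[0, 0] == pytest.approx(1.5 * (0.5 / 1.5) / (1e-3 + 1.5))
        assert new.m[1, 0] == pytest.approx(1.5 * (2.5 / 1.5) / (1e-3 + 1.5))

    def test_zero_mass_state_keeps_prior(self):
        model = hmm.init_model(2, 2)
        Y = np.random.default_rng(0).normal(size=(5, 2))
        gamma = np.zeros((5, 2))
        gamma[:, 0] = 1.0
        post = hmm.StatePosterior(gamma, np.zeros((2, 2)), gamma[[0]].sum(0), 0.0)
        new = hmm.vb_m_step(post, Y, model)
        pri = model.priors
        assert new.beta[1] == pytest.approx(pri.beta)
        assert new.nu[1] == pytest.approx(pri.dof)
        assert np.allclose(new.m[1], pri.mean)
        assert np.allclose(np.linalg.inv(new.W[1]), pri.scale_inv)

    def test_duplicate_states_get_identical_updates(self):
        model = hmm.init_model(2, 2)
        Y = np.random.default_rng(1).normal(size=(20, 2))
        gamma = np.full((20, 2), 0.5)
        post = hmm.StatePosterior(gamma, np.full((2, 2), 4.75), gamma[[0]].sum(0), 0.0)
        new = hmm.vb_m_step(post, Y, model)
        assert np.allclose(new.m[0], new.m[1])
        assert np.allclose(new.W[0], new.W[1])


class TestFreeEnergy:
    def test_monotone_decrease_over_iterations(self, gt3_data):
        obs, _ = gt3_data
        model, post = hmm.fit_hmm(obs, 3, n_restarts=1, max_iter=50, tol=0.0, seed=0)
        f = np.array(post.free_energy_trace)
        assert np.all(np.diff(f) <= 1e-6 * np.abs(f[:-1]))

    def test_invariant_under_relabeling(self):
        from dataclasses import replace

        model = arbitrary_model(3, 2, seed=9)
        Y = np.random.default_rng(9).normal(size=(25, 2))
        post = hmm.vb_e_step(model, Y)
        f = hmm.free_energy(model, post)
        perm = np.array([1, 2, 0])
        permuted = replace(
            model,
            trans_alpha=model.trans_alpha[np.ix_(perm, perm)],
            init_alpha=model.init_alpha[perm],
            beta=model.beta[perm],
            m=model.m[perm],
            W=model.W[perm],
            nu=model.nu[perm],
        )
        f2 = hmm.free_energy(permuted, hmm.vb_e_step(permuted, Y))
        assert f2 == pytest.approx(f, abs=1e-8)

    def test_single_state_matches_conjugate_evidence(self):
        """For K=1 the variational bound is tight: F must equal the negative
        closed-form Normal-Wishart log marginal likelihood."""
        rng = np.random.default_rng(10)
        T, M = 150, 3
        Y = rng.normal(0.4, 1.3, size=(T, M))
        model, post = hmm.fit_hmm(Y, 1, n_restarts=1, max_iter=5, seed=0)
        pri = model.priors
        ybar = Y.mean(0)
        S = (Y - ybar).T @ (Y - ybar)
        betaN, nuN = pri.beta + T, pri.dof + T
        d = ybar - pri.mean
        TN = pri.scale_inv + S + (pri.beta * T / betaN) * np.outer(d, d)
        _, ld0 = np.linalg.slogdet(pri.scale_inv)
        _, ldN = np.linalg.slogdet(TN)
        lml = (
            -(T * M / 2) * np.log(np.pi)
            + multigammaln(nuN / 2, M)
            - multigammaln(pri.dof / 2, M)
            + (pri.dof / 2) * ld0
            - (nuN / 2) * ldN
            + (M / 2) * np.log(pri.beta / betaN)
        )
        assert post.free_energy_trace[-1] == pytest.approx(-lml, abs=1e-6)


class TestFit:
    def test_fixed_seed_is_bit_identical(self, gt3_data):
        obs, _ = gt3_data
        m1, p1 = hmm.fit_hmm(obs[:500], 2, n_restarts=1, max_iter=20, seed=3)
        m2, p2 = hmm.fit_hmm(obs[:500], 2, n_restarts=1, max_iter=20, seed=3)
        assert np.array_equal(m1.m, m2.m)
        assert np.array_equal(m1.W, m2.W)
        assert p1.free_energy_trace == p2.free_energy_trace

    def test_best_restart_is_argmin(self, gt3_data):
        """The returned free energy cannot exceed that of the first restart,
        which a single-restart fit with the same seed reproduces exactly."""
        obs, _ = gt3_data
        _, p_multi = hmm.fit_hmm(obs[:800], 3, n_restarts=3, max_iter=30, seed=4)
        _, p_single = hmm.fit_hmm(obs[:800], 3, n_restarts=1, max_iter=30, seed=4)
        assert p_multi.free_energy_trace[-1] <= p_single.free_energy_trace[-1] + 1e-9

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            hmm.fit_hmm(np.ones((50, 2)), 2, n_restarts=1, seed=0)


class TestViterbi:
    def test_matches_exhaustive_maximization(self):
        model = arbitrary_model(3, 2, seed=11)
        Y = np.random.default_rng(11).normal(size=(8, 2))
        _, _, best = enumerate_posterior(model, Y)
        path = hmm.viterbi_decode(model, Y)
        assert np.array_equal(path.states, best)

    def test_well_separated_states_recovered_exactly(self, gt3, gt3_data):
        obs, true_path = gt3_data
        model, _ = hmm.fit_hmm(obs, 3, n_restarts=3, seed=1)
        dec = hmm.viterbi_decode(model, obs)
        perm = hmm.align_states(model.expected_means(), gt3.state_means)
        assert np.mean(perm[true_path.states] == dec.states) > 0.99

    def test_single_state_constant_path(self):
        model = arbitrary_model(1, 2, seed=12)
        Y = np.random.default_rng(12).normal(size=(30, 2))
        assert np.all(hmm.viterbi_decode(model, Y).states == 0)


def test_forward_backward_against_hmmlearn():
    """Independent cross-check of the chain recursions: with fixed Gaussian
    parameters (not expected-log VB quantities) our forward-backward must
    reproduce hmmlearn's posterior marginals."""
    hmmlearn_hmm = pytest.importorskip("hmmlearn.hmm")
    from scipy.stats import multivariate_normal

    from envhmm._recursions import forward_backward

    rng = np.random.default_rng(13)
    K, M, T = 3, 2, 200
    means = rng.normal(size=(K, M))
    A = rng.dirichlet(np.ones(K) * 3, size=K)
    pi = rng.dirichlet(np.ones(K))
    X = rng.normal(size=(T, M))
    log_b = np.column_stack(
        [multivariate_normal(means[k], np.eye(M)).logpdf(X) for k in range(K)]
    )
    gamma, _, _, _ = forward_backward(log_b, np.log(A), np.log(pi), np.array([T]))

    ref = hmmlearn_hmm.GaussianHMM(n_components=K, covariance_type="spherical", init_params="")
    ref.startprob_ = pi
    ref.transmat_ = A
    ref.means_ = means
    ref.covars_ = np.ones(K)
    ref_gamma = ref.predict_proba(X)
    assert np.abs(gamma - ref_gamma).max() < 1e-8


@pytest.fixture(scope="module")
def sweep_table():
    rng = np.random.default_rng(30)
    K, M = 4, 6
    means = rng.normal(size=(K, M)) * 2.0
    gt = synthetic.GroundTruth(
        transition_matrix=synthetic.transition_matrix_from_lifetime(K, 8),
        initial_probs=np.ones(K) / K,
        state_means=means,
        state_covs=np.tile(np.eye(M), (K, 1, 1)),
    )
    obs, _ = synthetic.simulate_gaussian_hmm(gt, 6000, seed=31, sampling_rate=40.0)
    return hmm.model_order_sweep(obs, [1, 4, 8], n_restarts=2, seed=32)


class TestModelOrderSweep:
    def test_one_finite_row_per_order(self, sweep_table):
        assert list(sweep_table["n_states"]) == [1, 4, 8]
        assert np.all(np.isfinite(sweep_table[["free_energy", "min_fractional_occupancy", "mean_life_time"]].values))

    def test_state_splitting_reduces_minimum_occupancy(self, sweep_table):
        t = sweep_table.set_index("n_states")
        assert t.loc[8, "min_fractional_occupancy"] <= t.loc[4, "min_fractional_occupancy"]

    def test_true_order_beats_single_state(self, sweep_table):
        t = sweep_table.set_index("n_states")
        assert t.loc[4, "free_energy"] <= t.loc[1, "free_energy"]
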