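"""Shared fixtures: small ground-truth models and simulated datasets."""

import numpy as np
import pytest

from envhmm import synthetic


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def gt3():
    """Well-separated 3-state Gaussian HMM (5-dim observations)."""
    return synthetic.GroundTruth(
        transition_matrix=synthetic.transition_matrix_from_lifetime(3, 10),
        initial_probs=np.ones(3) / 3,
        state_means=np.eye(3, 5) * 3.0,
        state_covs=np.tile(np.eye(5), (3, 1, 1)),
        seed=0,
    )


@pytest.fixture(scope="session")
def gt3_data(gt3):
    """(observations, path) from the 3-state fixture, T=3000."""
    return synthetic.simulate_gaussian_hmm(gt3, 3000, seed=7)


@pytest.fixture(scope="session")
def envelope_fixture():
    """Envelope dataset with 3 localized topographies plus a quiescent
    background state occupying roughly half the time (as transient
    states do in resting-state data)."""
    rng = np.random.default_rng(21)
    K, V = 4, 48
    topo = np.zeros((K, V))
    for k in range(3):
        topo[k, k * 12 : (k + 1) * 12] = np.abs(rng.normal(1.0, 0.25, size=12))
    dataset, path = synthetic.simulate_envelope_dataset(
        topo,
        baseline_level=2.0,
        mean_lifetime_samples=8,
        n_subjects=3,
        samples_per_subject=8000,
        noise_sd=0.4,
        seed=5,
        relative_occupancy=[1, 1, 1, 4],
    )
    return dataset, path, topo
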